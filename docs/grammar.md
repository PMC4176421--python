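# Instruction-string grammar

One glyph is specified by a single instruction string stored in a node-table
column. The grammar, in EBNF (terminals quoted):

```ebnf
instruction   = prefix , ":" , { ws , argument } ;
prefix        = "lingrad" | "radgrad"
              | "barchart" | "circoschart" | "heatstripchart"
              | "linechart" | "piechart" | "stripechart" ;
argument      = name , "=" , value ;
name          = letter , { letter | digit | "_" } ;
value         = quoted | bare ;
quoted        = '"' , { any character except '"' } , '"' ;
bare          = { any character except whitespace } ;
ws            = whitespace , { whitespace } ;
```

Quoted values may contain spaces, commas and `=`; single quotes are not
special. Prefixes are case-folded to lowercase before validation. Argument
names are unique within one instruction.

## Typed argument values

```ebnf
number        = [ "+" | "-" ] , ( digits , [ "." , digits ] | "." , digits ) ;
                (* plain literals only; no exponent notation *)
boolean       = "true" | "false" ;
proportion    = number in [0, 1] ;
point         = proportion , "," , proportion ;                 (* "x,y" *)
color         = css-name | "#RRGGBB" | "#RRGGBBAA" ;            (* hex case-insensitive *)
value-list    = number , { "," , number } ;
name-list     = name , { "," , name } ;
range         = number , "," , number ;                          (* min < max *)
ybase         = "top" | "middle" | "bottom" | proportion ;
labelstyle    = "italics" | "bold" | "bolditalic" | "plain" ;
stop          = byte , "," , byte , "," , byte , "," , byte , "," , proportion ;
                (* r,g,b,a each in [0,255] *)
stoplist      = stop , { "|" , stop } ;
colorlist     = "contrasting" | "modulated" | "rainbow" | "random"
              | gradient-kw
              | updown
              | color , { "," , color } ;
gradient-kw   = "yellowcyan" | "yellowblue" | "orangepurple"
              | "bluegreenyellow" | "purpleyellow" | "greenpurple"
              | "redyellow" | "redgreen" ;
updown        = "up:" color , ",down:" , color , [ ",zero:" , color ] ;
```

## Arguments per prefix

Common arguments (`attributelist`, `values`, `labels`, `labelcolor`,
`labelfont`, `labelsize`, `labelstyle`, `range`, `scale`, `showlabels`,
`ybase`, `colorlist`) are accepted by `barchart`, `heatstripchart` and
`linechart`. `piechart` and `circoschart` accept them **except** `range`,
`scale` and `ybase`. `stripechart` accepts only `colorlist` (required).
`values` and `attributelist` are mutually exclusive.

| Prefix | Own arguments |
|---|---|
| `lingrad` | `start` (point), `end` (point), `stoplist` (required) |
| `radgrad` | `center` (point), `radius` (proportion), `stoplist` (required) |
| `barchart` | `separation` (number, reference units of a 100-wide box) |
| `circoschart` | `arcstart` (degrees), `arcwidth`, `firstarc`, `firstarcwidth` (proportions), `labelcircles`, `sortslices` (booleans) |
| `heatstripchart` | `separation`; its `colorlist` must be a gradient keyword or up/down colors |
| `linechart` | `linewidth` (number, reference units) |
| `piechart` | `arcstart` (degrees), `sortslices` (boolean) |
| `stripechart` | — |

Any argument outside these sets is an error: a recognised name used with the
wrong prefix raises a forbidden-argument error; an unrecognised name raises
an unknown-argument error.
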