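<?xml version='1.0' encoding='utf-8'?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="100" height="100" viewBox="0 0 100 100"><defs /><g id="edges" stroke="#999999" stroke-width="1" /><g id="nodes"><g id="node-n1"><ellipse cx="50" cy="50" rx="30" ry="30" fill="#e8e8e8" stroke="#555555" stroke-width="1" /><path d="M 50 50 L 50 20 A 30 30 0 0 1 80 50 Z" fill="#ff0000" /><path d="M 50 50 L 80 50 A 30 30 0 0 1 50 80 Z" fill="#00ff00" /><path d="M 50 50 L 50 80 A 30 30 0 0 1 50 20 Z" fill="#0000ff" /></g></g></svg>
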