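# Brand -> generic name map applied during drug-name normalization.
# Keys are matched as whole uppercased tokens; extend freely.
AVASTIN: BEVACIZUMAB
MVASI: BEVACIZUMAB
ZIRABEV: BEVACIZUMAB
TEMODAR: TEMOZOLOMIDE
TEMODAL: TEMOZOLOMIDE
GLEOSTINE: LOMUSTINE
CEENU: LOMUSTINE
BICNU: CARMUSTINE
GLIADEL: CARMUSTINE
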