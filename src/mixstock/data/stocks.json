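{
  "stocks": {
    "BRA": ["BRA"],
    "NWCG": ["ACR", "FLA", "DR"],
    "STX": ["STX"],
    "SECG": ["TRI", "GUI", "FWI"],
    "GHA": ["GHA"],
    "GAB": ["GAB"],
    "SAF": ["SAF"]
  }
}
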