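{
  "description": "Five-step rearrangement history from the pancrustacean ground pattern to the Pisidia serratifrons gene order: two tandem-duplication/random-loss events followed by four block translocations.",
  "source": "cox1 trnL2 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4l trnT -trnP nad6 cob trnS2 -nad1 -trnL1 -rrnL -trnV -rrnS CR trnI -trnQ trnM nad2 trnW -trnC -trnY",
  "target": "cox1 trnL2 cox2 trnK trnG nad3 trnA -trnF -nad5 -trnH -nad4 -nad4l trnT nad6 cob trnS2 -trnP -nad1 -trnL1 -rrnL -trnV -rrnS CR trnM trnI nad2 trnD atp8 atp6 cox3 trnR trnN trnS1 trnE trnW -trnQ -trnC -trnY",
  "ops": [
    {
      "kind": "tdrl",
      "block": ["trnD", "atp8", "atp6", "cox3", "trnG", "nad3", "trnA"],
      "keep": {"trnD": 2, "atp8": 2, "atp6": 2, "cox3": 2, "trnG": 1, "nad3": 1, "trnA": 1}
    },
    {
      "kind": "translocate_block",
      "block": ["trnD", "atp8", "atp6", "cox3"],
      "after": "nad2"
    },
    {
      "kind": "tdrl",
      "block": ["trnI", "trnQ", "trnM"],
      "keep": {"trnI": 2, "trnQ": 2, "trnM": 1}
    },
    {
      "kind": "translocate_block",
      "block": ["trnQ"],
      "after": "trnW"
    },
    {
      "kind": "translocate_block",
      "block": ["trnR", "trnN", "trnS1", "trnE"],
      "before": "trnW"
    },
    {
      "kind": "translocate_block",
      "block": ["trnP"],
      "after": "trnS2"
    }
  ]
}
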