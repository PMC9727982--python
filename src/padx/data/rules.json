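{
  "comment": "Default diagnostic-element matching rules for pituitary-adenoma discharge diagnoses. literal rules match the full surface of a token or nested sub-entity (case-insensitive); regex rules match the raw text (multiword phrases, hormone combinations); Knosp grades are parsed by the dedicated parser at priority 100.",
  "rules": [
    {
      "element": "tumor_recurrence",
      "kind": "literal",
      "priority": 10,
      "values": ["复发", "复发性", "再发", "recurrent", "recurrence"]
    },
    {
      "element": "tumor_location",
      "kind": "literal",
      "priority": 10,
      "values": ["垂体", "异位垂体", "鞍区", "pituitary", "ectopic", "sellar"]
    },
    {
      "element": "invasiveness",
      "kind": "literal",
      "priority": 10,
      "values": ["侵袭性", "侵袭", "invasive", "aggressive"]
    },
    {
      "element": "endocrine_status",
      "kind": "literal",
      "priority": 10,
      "values": [
        "无功能", "无功能性", "nonfunctioning", "non-functioning",
        "ACTH分泌型", "GH分泌型", "PRL分泌型", "TSH分泌型", "FSH分泌型", "LH分泌型",
        "ACTH型", "GH型", "PRL型", "TSH型",
        "促肾上腺皮质激素分泌型", "生长激素分泌型", "泌乳素分泌型",
        "促甲状腺激素分泌型", "促性腺激素分泌型",
        "GH/PRL混合型", "GH/TSH混合型", "ACTH/GH混合型", "FSH/LH混合型",
        "GH/PRL/TSH混合型",
        "ACTH", "GH", "TSH", "PRL", "FSH", "LH"
      ]
    },
    {
      "element": "endocrine_status",
      "kind": "regex",
      "priority": 10,
      "pattern": "(?<![A-Za-z])(?:ACTH|GH|TSH|PRL|FSH|LH)(?:/(?:ACTH|GH|TSH|PRL|FSH|LH))+(?:\\s+mixed)?(?![A-Za-z])"
    },
    {
      "element": "endocrine_status",
      "kind": "regex",
      "priority": 20,
      "pattern": "(?<![A-Za-z])(?:growth hormone|adrenocorticotropic hormone|thyroid[ -]stimulating hormone|prolactin)(?:[ -]secreting)?(?![A-Za-z])"
    },
    {
      "element": "tumor_size",
      "kind": "literal",
      "priority": 10,
      "values": ["微", "大", "巨大", "micro", "macro", "giant"]
    },
    {
      "element": "histopathology",
      "kind": "literal",
      "priority": 10,
      "values": ["腺瘤", "adenoma"]
    },
    {
      "element": "residual_tumor",
      "kind": "literal",
      "priority": 10,
      "values": ["残留", "肿瘤残留", "术后残留", "部分切除"]
    },
    {
      "element": "residual_tumor",
      "kind": "regex",
      "priority": 20,
      "pattern": "(?<![A-Za-z])incomplete resection(?![A-Za-z])|(?<![A-Za-z])residual tumou?r(?![A-Za-z])"
    },
    {
      "element": "diagnostic_confirmation",
      "kind": "literal",
      "priority": 10,
      "values": ["拟诊", "可能", "疑诊", "待查", "probable", "suspected"]
    },
    {
      "element": "diagnostic_confirmation",
      "kind": "regex",
      "priority": 20,
      "pattern": "(?<![A-Za-z])highly suspected(?![A-Za-z])"
    },
    {
      "element": "refractoriness",
      "kind": "literal",
      "priority": 10,
      "values": ["难治性", "难治", "refractory"]
    }
  ]
}
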