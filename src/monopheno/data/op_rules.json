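{
  "description": "Expression-profile (OP) rule table. Each rule is a conjunction of per-marker bin clauses; 'mfi' lists admissible MFI bins (null = any), 'pct' lists admissible percent-positive bins (null = any). Rules are evaluated most-specific first (clause count, then op id); placeholder rules with no clauses are never matched and exist only so that the profile ids printed in the donor-connectivity table resolve.",
  "rules": [
    {"op_id": "OP-01", "subpopulation": "sm14+16neg", "clauses": [
      {"marker": "CD49d", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD162", "mfi": ["bri", "med"], "pct": ["hi"]}]},
    {"op_id": "OP-02", "subpopulation": "sm14+16neg", "clauses": [
      {"marker": "CD49d", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD162", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD62L", "mfi": ["med"], "pct": ["hi"]}]},
    {"op_id": "OP-03", "subpopulation": "sm14+16neg", "clauses": [
      {"marker": "CD49d", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD162", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["dim"], "pct": ["lo"]}]},
    {"op_id": "OP-04", "subpopulation": "sm14+16neg", "clauses": [
      {"marker": "CD49d", "mfi": ["med"], "pct": ["int"]},
      {"marker": "CD43", "mfi": ["dim"], "pct": null},
      {"marker": "CD162", "mfi": ["bri"], "pct": ["hi"]},
      {"marker": "CD62L", "mfi": ["bri"], "pct": ["hi"]}]},
    {"op_id": "OP-05", "subpopulation": "sm14+16neg", "clauses": [
      {"marker": "CD49d", "mfi": ["med"], "pct": ["int", "lo"]},
      {"marker": "CD43", "mfi": ["med", "dim"], "pct": null},
      {"marker": "CD162", "mfi": ["bri"], "pct": ["hi"]},
      {"marker": "CD62L", "mfi": ["bri"], "pct": ["hi"]}]},

    {"op_id": "OP-10", "subpopulation": "la14+16neg", "clauses": [
      {"marker": "CD49d", "mfi": ["bri"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["dim"], "pct": ["hi"]}]},
    {"op_id": "OP-11", "subpopulation": "la14+16neg", "clauses": [
      {"marker": "CD49d", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["med", "dim"], "pct": ["hi"]}]},
    {"op_id": "OP-12", "subpopulation": "la14+16neg", "clauses": [
      {"marker": "CD49d", "mfi": ["bri"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["dim"], "pct": ["int"]}]},

    {"op_id": "OP-20", "subpopulation": "sm14+16+", "clauses": [
      {"marker": "CD49d", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD162", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["dim"], "pct": ["hi"]},
      {"marker": "CD62L", "mfi": ["med"], "pct": ["hi"]}]},
    {"op_id": "OP-21", "subpopulation": "sm14+16+", "clauses": [
      {"marker": "CD49d", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD162", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["med"], "pct": ["hi"]}]},
    {"op_id": "OP-22", "subpopulation": "sm14+16+", "clauses": [
      {"marker": "CD49d", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD162", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["dim"], "pct": ["hi"]},
      {"marker": "CD62L", "mfi": null, "pct": ["hi"]}]},

    {"op_id": "OP-30", "subpopulation": "la14+16+", "clauses": [
      {"marker": "CD49d", "mfi": ["bri"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["dim"], "pct": ["hi"]}]},
    {"op_id": "OP-31", "subpopulation": "la14+16+", "clauses": [
      {"marker": "CD49d", "mfi": ["bri"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["med"], "pct": ["hi"]}]},
    {"op_id": "OP-32", "subpopulation": "la14+16+", "clauses": [
      {"marker": "CD49d", "mfi": ["bri", "med"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["med", "dim"], "pct": ["hi"]}]},
    {"op_id": "OP-33", "subpopulation": "la14+16+", "clauses": [
      {"marker": "CD49d", "mfi": ["bri"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["bri"], "pct": ["hi"]}]},

    {"op_id": "OP-40", "subpopulation": "sm14dim16+", "clauses": [
      {"marker": "CD49d", "mfi": ["bri"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["dim"], "pct": ["hi"]},
      {"marker": "CD162", "mfi": ["bri"], "pct": ["hi"]}]},
    {"op_id": "OP-41", "subpopulation": "sm14dim16+", "clauses": [
      {"marker": "CD49d", "mfi": ["bri"], "pct": ["hi"]},
      {"marker": "CD43", "mfi": ["med"], "pct": ["hi"]}]},
    {"op_id": "OP-42", "subpopulation": "sm14dim16+", "placeholder": true, "clauses": [
      {"marker": "CD49d", "mfi": ["med"], "pct": ["hi"]},
      {"marker": "CD162", "mfi": ["bri", "med"], "pct": ["hi"]}]},
    {"op_id": "OP-43", "subpopulation": "sm14dim16+", "placeholder": true, "clauses": []},
    {"op_id": "OP-44", "subpopulation": "sm14dim16+", "placeholder": true, "clauses": []},

    {"op_id": "OP-50", "subpopulation": "sm14dim16neg", "clauses": [
      {"marker": "CD49d", "mfi": ["med"], "pct": ["hi"]},
      {"marker": "CD62L", "mfi": ["dim"], "pct": ["int", "lo"]}]},
    {"op_id": "OP-51", "subpopulation": "sm14dim16neg", "clauses": [
      {"marker": "CD49d", "mfi": ["med"], "pct": ["int", "lo"]},
      {"marker": "CD62L", "mfi": ["med"], "pct": ["hi", "int"]}]}
  ]
}
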