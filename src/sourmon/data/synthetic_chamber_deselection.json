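{
  "schema": "sourmon.deselection.v1",
  "description": "Synthetic stand-in deselection layout for the 47x15 chamber grid: a one-region border ring (uneven chamber edges, 120 regions) plus a 13x6 central block over the in-situ oxygen sensor (78 regions), discarding 198 of 705 regions. The layout is constructed, not measured; real runs supply their own exclusion zones.",
  "rows": 47,
  "cols": 15,
  "border": 1,
  "blocks": [[17, 30, 4, 10]]
}
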