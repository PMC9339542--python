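{
  "schema": "dcflow-circuit/1",
  "metadata": {
    "name": "BG5",
    "species": "rat",
    "pathway": "basal ganglia loop, direct pathway"
  },
  "nodes": [
    {"name": "Cortex", "target_cell_count": 5000000, "region_volume_mm3": 470},
    {"name": "Thalamus", "target_cell_count": 10638, "region_volume_mm3": 485},
    {"name": "Striatum", "target_cell_count": 765957, "region_volume_mm3": 72},
    {"name": "GPi/SNr", "target_cell_count": 3830, "region_volume_mm3": 66},
    {"name": "SNc", "target_cell_count": 5426, "region_volume_mm3": 4.34}
  ],
  "edges": [
    {"source": "Cortex", "target": "Striatum"},
    {"source": "Striatum", "target": "GPi/SNr"},
    {"source": "GPi/SNr", "target": "Thalamus"},
    {"source": "Thalamus", "target": "Cortex"},
    {"source": "SNc", "target": "Striatum"}
  ]
}
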