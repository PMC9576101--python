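{
  "comment": "Material manifest: table file + nominal mass density (g/cm^3). Densities are ICRU-44 nominal tissue densities; override via load_material_library(density_overrides=...).",
  "materials": {
    "air": {"table": "air_dry.tsv", "rho_ref": 0.001205},
    "water": {"table": "water_liquid.tsv", "rho_ref": 1.0},
    "adipose": {"table": "adipose_icru44.tsv", "rho_ref": 0.95},
    "blood": {"table": "blood_icru44.tsv", "rho_ref": 1.06},
    "skeletal_muscle": {"table": "skeletal_muscle_icru44.tsv", "rho_ref": 1.05},
    "cortical_bone": {"table": "cortical_bone_icru44.tsv", "rho_ref": 1.92}
  },
  "aliases": {"muscle": "skeletal_muscle", "bone": "cortical_bone", "fat": "adipose"}
}
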