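{
  "comment": "Orthotropic elastic constants of the mandible FE components (MPa). The voxel solver is isotropic; 'materials.json' carries the isotropic reductions actually used (Ex row for host cortical bone).",
  "components": [
    {"name": "cortical_symphysis", "Ex": 23000, "Ey": 15000, "Ez": 10000, "nu_xy": 0.3, "nu_yz": 0.3, "nu_xz": 0.3},
    {"name": "cortical_angle", "Ex": 20000, "Ey": 12000, "Ez": 11000, "nu_xy": 0.3, "nu_yz": 0.3, "nu_xz": 0.3},
    {"name": "cortical_rest", "Ex": 17000, "Ey": 8200, "Ez": 6900, "nu_xy": 0.315, "nu_yz": 0.325, "nu_xz": 0.31},
    {"name": "cancellous", "Ex": 960, "Ey": 390, "Ez": 320, "nu_xy": 0.3, "nu_yz": 0.3, "nu_xz": 0.3},
    {"name": "cortical_fibular_graft", "Ex": 26800, "Ey": 26800, "Ez": 26800, "nu_xy": 0.3, "nu_yz": 0.3, "nu_xz": 0.3},
    {"name": "cancellous_fibular_graft", "Ex": 1650, "Ey": 1650, "Ez": 1650, "nu_xy": 0.3, "nu_yz": 0.3, "nu_xz": 0.3},
    {"name": "teeth", "Ex": 17600, "Ey": 17600, "Ez": 17600, "nu_xy": 0.25, "nu_yz": 0.25, "nu_xz": 0.25},
    {"name": "periodontal_ligament", "Ex": 2.7, "Ey": 2.7, "Ez": 2.7, "nu_xy": 0.45, "nu_yz": 0.45, "nu_xz": 0.45},
    {"name": "ti6al4v", "Ex": 112000, "Ey": 112000, "Ez": 112000, "nu_xy": 0.3, "nu_yz": 0.3, "nu_xz": 0.3},
    {"name": "niti_dense", "Ex_range": [37000, 42000], "nu_xy": 0.3, "comment": "austenite 37 GPa / martensite 42 GPa; linearized runs default to the austenite value"}
  ]
}
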