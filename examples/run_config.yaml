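# Example run configuration for `baltisim validate`.
geometry_path: mini8          # shipped geometry name or a JSON path
forcing_path: ""              # empty: generate synthetically from the seed
groups_path: ""               # empty: use the built-in group catalog
availability_path: ""
scenario_name: s5_pan_baltic
years: 60
ecological_timestep: 1.0      # days
physics_timestep: 12.0        # hours; must divide 24 evenly
seed: 1
output_path: out/
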