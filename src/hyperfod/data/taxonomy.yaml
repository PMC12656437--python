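# Material taxonomy for pork-belly foreign-object detection.
#
# 13 classes: three background materials (the pork belly itself plus the
# conveyor it travels on) and ten contaminant materials.  Class order is
# canonical and index-stable: background classes come first, which keeps
# loss-weight configuration simple.  The display palette is package
# plumbing for rendering masks; index 255 marks unannotated pixels.
classes:
  - {index: 0,  name: meat,          role: background,  color: "#8c1c1c"}
  - {index: 1,  name: fat,           role: background,  color: "#f2d8c0"}
  - {index: 2,  name: conveyor_belt, role: background,  color: "#3c4450"}
  - {index: 3,  name: pa_pp,         role: contaminant, color: "#1f77b4"}
  - {index: 4,  name: pu,            role: contaminant, color: "#ff7f0e"}
  - {index: 5,  name: metal,         role: contaminant, color: "#7f7f7f"}
  - {index: 6,  name: pehd,          role: contaminant, color: "#2ca02c"}
  - {index: 7,  name: teflon,        role: contaminant, color: "#d62728"}
  - {index: 8,  name: nitrile,       role: contaminant, color: "#9467bd"}
  - {index: 9,  name: wood,          role: contaminant, color: "#8c564b"}
  - {index: 10, name: paper,         role: contaminant, color: "#e377c2"}
  - {index: 11, name: cardboard,     role: contaminant, color: "#bcbd22"}
  - {index: 12, name: white_belt,    role: contaminant, color: "#17becf"}
unannotated_index: 255
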