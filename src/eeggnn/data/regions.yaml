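# Assignment of the 16-channel referential montage to the five anatomical
# regions used for attention pooling.  Edit or replace via RegionMap.from_yaml.
frontal: [FP1, FP2, F3, F4, F7, F8]
central: [C3, C4]
parietal: [P3, P4]
occipital: [O1, O2]
temporal: [T3, T4, T5, T6]
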