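label,n_exposed,n_exposed_diagnosed
Skull,1,0
Head,9,4
Neurological-Brain,60,33
Neurological-Functional,82,40
Neural Tube Defect,8,4
Eye,29,19
Ear,4,2
Nose,4,2
Oral Cavity,42,23
Neck,2,2
Throat,34,10
Chest,4,1
Lung,22,10
Gastrointestinal,97,34
Renal,97,33
Liver-Biliary,45,9
Spleen,45,6
Ribs-Vertebral,38,8
Limb-Digit,49,24
Skin,4,3
Umbilical,8,1
Immunologic,3,2
Endocrine,17,10
Growth-Feeding,75,34
Hematologic,9,6
Other,18,6
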