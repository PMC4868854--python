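{
 "cluster_composition.csv": "8e3a2e806db0bda098462a8684c9839dba9f8fd9d1c6246607ec9410107482a9",
 "effect_sizes.csv": "c9ec9782edeb4e6e1452a844c60fd288803728e13665e0ba15f3a49ebbbfeb1c"
}
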