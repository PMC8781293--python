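77683a3d1412781ea8da705e069f6c03bb478cf43f87308ba989e1f193c167ff  table1_test_set.tsv
02649ac6758ae24b9ad4cf8770f8fd7b156a78c133cf9ee599a3d5ecee23bf91  table2_positioning.tsv
428cf2a136c8bb7c0522e0c33f97d321032a92cda6c1c178f5b5a2905c643112  table3_enthalpy.tsv
0849f0cf42e382a603c73276bdf4978b8e6722e7fe547f1f3b53b4f490881ebf  evaluation_metadata.yaml
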