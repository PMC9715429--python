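source_label,canonical_label
Globigerinoides ruber ruber,Globigerinoides ruber
Globigerinoides ruber albus,Globigerinoides ruber
Globigerinoides ruber (pink),Globigerinoides ruber
Globigerinoides ruber (white),Globigerinoides ruber
G. ruber ruber,Globigerinoides ruber
G. ruber albus,Globigerinoides ruber
P/D intergrade,Neogloboquadrina incompta
P/D intergrades,Neogloboquadrina incompta
Neogloboquadrina pachyderma (dextral),Neogloboquadrina incompta
Neogloboquadrina pachyderma (sinistral),Neogloboquadrina pachyderma
Globigerinoides sacculifer,Trilobatus sacculifer
Globigerinella aequilateralis,Globigerinella siphonifera
Globigerina digitata,Beella digitata
Globigerina quinqueloba,Turborotalita quinqueloba
Globorotalia cultrata,Globorotalia menardii
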