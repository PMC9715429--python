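canonical_label
Orbulina universa
Globigerinoides conglobatus
Globigerinoides ruber
Globigerinoides elongatus
Trilobatus sacculifer
Sphaeroidinella dehiscens
Globigerinella siphonifera
Globigerinella calida
Globigerinella adamsi
Globigerina bulloides
Globigerina falconensis
Beella digitata
Globoturborotalita rubescens
Globoturborotalita tenella
Turborotalita quinqueloba
Turborotalita humilis
Neogloboquadrina pachyderma
Neogloboquadrina incompta
Neogloboquadrina dutertrei
Globoquadrina conglomerata
Pulleniatina obliquiloculata
Globorotalia inflata
Globorotalia truncatulinoides
Globorotalia crassaformis
Globorotalia hirsuta
Globorotalia scitula
Globorotalia theyeri
Globorotalia menardii
Globorotalia tumida
Globorotalia ungulata
Globorotaloides hexagonus
Candeina nitida
Globigerinita glutinata
Globigerinita uvula
Globigerinita minuta
Tenuitella iota
Tenuitella parkerae
Hastigerina pelagica
Hastigerinella digitata
Berggrenia pumilio
Globorotalia cavernula
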