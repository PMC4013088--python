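code,species,family,year_established,years_established,n_records,risk_assessment_score
CliHir,Clidemia hirta,Melastomataceae,1941,72,60,27
FalMol,Falcataria moluccana,Fabaceae,1920,93,414,8
HedGar,Hedychium gardnerianum,Zingiberaceae,1940,73,218,16
LanCam,Lantana camara,Verbenaceae,1858,155,307,32
LeuLeu,Leucaena leucocephala,Fabaceae,1837,176,502,15
MelMin,Melinis minutiflora,Poaceae,1910,103,298,18
MicCal,Miconia calvescens,Melastomataceae,1983,30,102595,14
MorFay,Morella faya,Myricaceae,1926,87,968,17
PanMax,Panicum maximum,Poaceae,1871,142,44,17
PasTar,Passiflora tarminiana,Passifloraceae,1926,87,5857,24
PenCla,Pennisetum clandestinum,Poaceae,1923,90,135,18
PenSet,Pennisetum setaceum,Poaceae,1914,99,317,26
PsiCat,Psidium cattleianum,Myrtaceae,1825,188,540,18
SchTer,Schinus terebinthifolius,Anacardiaceae,1911,102,916,19
SetPal,Setaria palmifolia,Poaceae,1903,110,1059,7
SphCoo,Sphaeropteris cooperi,Cyatheaceae,1950,63,79,8
UleEur,Ulex europaeus,Fabaceae,1914,99,473,20
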