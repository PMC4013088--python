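name,baseline_km2,future_km2,ch_baseline_km2,ch_future_km2
PasTar,5114.63,6309.72,649.81,670.65
HedGar,509.41,3542.27,292.07,709.04
LanCam,2010.76,3003.88,340.07,723.31
PsiCat,1901.38,2454.60,483.65,646.56
PenCla,2063.50,2391.00,339.40,440.96
MicCal,2084.09,2137.24,317.67,425.02
PenSet,1954.18,1953.67,214.23,151.51
MelMin,1049.23,1737.33,313.48,441.14
SphCoo,425.97,1241.47,53.27,277.50
SchTer,959.42,1176.02,196.71,213.48
LeuLeu,727.21,1046.33,55.72,118.00
FalMol,470.24,804.67,51.25,101.11
UleEur,164.40,724.52,106.31,260.28
CliHir,189.85,515.16,112.39,187.75
PanMax,263.71,248.04,22.74,15.71
MorFay,402.49,23.64,139.33,4.34
SetPal,297.74,0.26,152.19,0.26
E,14301.61,14225.09,2562.49,2545.79
AII,16138.70,,2910.76,
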