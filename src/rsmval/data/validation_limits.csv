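compound,group,matrix,cc_alpha_ugkg,cc_beta_ugkg,loq_ugkg
cinoxacin,quinolone,bacon,16.2,22.5,0.1
cinoxacin,quinolone,ham,20.2,30.3,0.05
ciprofloxacin,quinolone,bacon,24.7,39.4,2
ciprofloxacin,quinolone,ham,21.6,33.3,5
danofloxacin,quinolone,bacon,12.4,14.8,0.1
danofloxacin,quinolone,ham,24.4,38.8,0.2
difluoxacin,quinolone,bacon,22.4,34.8,1
difluoxacin,quinolone,ham,18.9,27.8,1
enoxacin,quinolone,bacon,16.4,22.9,0.5
enoxacin,quinolone,ham,26.3,42.6,0.1
enrofloxacin,quinolone,bacon,25.2,40.3,2
enrofloxacin,quinolone,ham,20.2,30.5,0.5
fleroxacin,quinolone,bacon,24.9,39.8,2
fleroxacin,quinolone,ham,21.7,33.4,10
flumequine,quinolone,bacon,15.5,21,0.1
flumequine,quinolone,ham,19.4,28.7,0.05
gatifloxacin,quinolone,bacon,20.5,31,0.2
gatifloxacin,quinolone,ham,27.6,45.2,1
gemifioxacin,quinolone,bacon,13.9,17.8,0.1
gemifioxacin,quinolone,ham,23.3,36.6,0.2
lomefloxacin,quinolone,bacon,20.9,31.8,1
lomefloxacin,quinolone,ham,23.3,36.6,5
marbofloxacin,quinolone,bacon,13.2,16.4,0.5
marbofloxacin,quinolone,ham,27.1,44.1,0.5
moxifloxacin,quinolone,bacon,11.8,13.7,1
moxifloxacin,quinolone,ham,31.3,52.5,0.5
nadifloxacin,quinolone,bacon,14.6,19.2,0.1
nadifloxacin,quinolone,ham,21.1,32.1,0.1
nalidixic acid,quinolone,bacon,15.1,20.2,0.2
nalidixic acid,quinolone,ham,17.3,24.6,0.1
ofloxacin,quinolone,bacon,25.9,41.8,2
ofloxacin,quinolone,ham,27.1,44.2,5
orbifloxacin,quinolone,bacon,23.8,37.7,5
orbifloxacin,quinolone,ham,29.4,48.8,2
oxolinic acid,quinolone,bacon,18,26,0.1
oxolinic acid,quinolone,ham,19.7,29.3,0.1
pefloxacin,quinolone,bacon,14.9,19.7,0.1
pefloxacin,quinolone,ham,24.0,38.0,0.5
sarafloxacin,quinolone,bacon,12.7,15.4,2
sarafloxacin,quinolone,ham,25.9,41.8,1
sparfloxacin,quinolone,bacon,25.7,41.3,1
sparfloxacin,quinolone,ham,23.2,36.3,1
sulfabenzamide,sulfonamide,bacon,15.4,20.8,0.05
sulfabenzamide,sulfonamide,ham,24.7,39.5,0.1
sulfachloropyridazine,sulfonamide,bacon,17.8,25.6,1
sulfachloropyridazine,sulfonamide,ham,25.1,40.1,2
sulfaclozine,sulfonamide,bacon,18.8,27.6,0.1
sulfaclozine,sulfonamide,ham,26.7,43.5,1
sulfadiazine,sulfonamide,bacon,11.6,13.3,0.05
sulfadiazine,sulfonamide,ham,16.5,23.0,0.1
sulfadimidine,sulfonamide,bacon,16.2,22.5,0.1
sulfadimidine,sulfonamide,ham,22.7,35.3,0.05
sulfadoxine,sulfonamide,bacon,12.8,15.6,0.1
sulfadoxine,sulfonamide,ham,24.6,39.3,0.05
sulfamerazine,sulfonamide,bacon,13.9,17.8,0.2
sulfamerazine,sulfonamide,ham,18.4,26.8,1
sulfameter,sulfonamide,bacon,11.9,13.9,0.2
sulfameter,sulfonamide,ham,25.7,41.5,1
sulfamethizole,sulfonamide,bacon,17.3,24.5,0.1
sulfamethizole,sulfonamide,ham,18.1,26.1,0.5
sulfamethoxazole,sulfonamide,bacon,14.2,18.4,0.05
sulfamethoxazole,sulfonamide,ham,20.6,31.3,0.05
sulfamethoxypyridazine,sulfonamide,bacon,16,22,0.1
sulfamethoxypyridazine,sulfonamide,ham,24.6,39.2,0.2
sulfamonomethoxine,sulfonamide,bacon,21.8,33.6,0.1
sulfamonomethoxine,sulfonamide,ham,21.4,32.7,0.2
sulfamoxole,sulfonamide,bacon,19.4,28.9,0.1
sulfamoxole,sulfonamide,ham,21.6,33.2,0.2
sulfaphenazole,sulfonamide,bacon,12.1,14.1,0.05
sulfaphenazole,sulfonamide,ham,20.6,31.1,0.05
sulfapyrazole,sulfonamide,bacon,12.7,15.3,0.1
sulfapyrazole,sulfonamide,ham,16.8,23.7,0.05
sulfapyridine,sulfonamide,bacon,15.5,20.9,0.05
sulfapyridine,sulfonamide,ham,19.2,28.3,0.2
sulfaquinoxaline,sulfonamide,bacon,16.3,22.5,0.05
sulfaquinoxaline,sulfonamide,ham,22.1,34.2,0.05
sulfathiazole,sulfonamide,bacon,10.9,11.8,0.1
sulfathiazole,sulfonamide,ham,18.1,26.1,0.05
sulfisomidine,sulfonamide,bacon,13.4,16.9,0.05
sulfisomidine,sulfonamide,ham,17.0,24.1,0.1
sulfisoxazole,sulfonamide,bacon,15.6,21.2,0.05
sulfisoxazole,sulfonamide,ham,18.8,27.6,0.05
sulfadimethoxine,sulfonamide,bacon,13.5,16.9,0.05
sulfadimethoxine,sulfonamide,ham,13.7,17.4,0.05
trimethoprim,sulfonamide,bacon,13.7,17.3,0.05
trimethoprim,sulfonamide,ham,20.7,31.4,0.5
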