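field,algorithm,precision_pct,recall_pct
HEN1,exg,18.0,94.7
HEN1,nexg,27.7,75.8
HEN1,hsv,22.6,76.3
HEN1,exhsv,37.9,71.6
HEN2,exg,46.5,73.2
HEN2,nexg,90.2,53.3
HEN2,hsv,87.7,50.5
HEN2,exhsv,94.4,54.4
WAG1,exg,91.8,73.8
WAG1,nexg,95.1,47.8
WAG1,hsv,96.6,39.9
WAG1,exhsv,99.1,47.7
WAG2,exg,70.2,68.1
WAG2,nexg,90.9,36.1
WAG2,hsv,91.0,48.8
WAG2,exhsv,91.1,43.4
COB1,exg,98.0,39.3
COB1,nexg,98.0,20.2
COB1,hsv,100.0,47.0
COB1,exhsv,100.0,23.1
NIGHT1,exg,64.5,48.9
NIGHT1,nexg,47.7,42.5
NIGHT1,hsv,100.0,23.8
NIGHT1,exhsv,80.6,34.7
NIGHT2,exg,96.4,62.7
NIGHT2,nexg,,
NIGHT2,hsv,100.0,35.7
NIGHT2,exhsv,90.6,76.6
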