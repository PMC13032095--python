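participant_id,tai_36,tai_44,tai_46,tai_48,vas_low_contrast_46,vas_high_contrast_46,contrast_magnitude,mean_vas_46,sensitivity_group
P0000,0.07160487974,-0.6657333962,15.75064659,41.26290642,11.73651139,15.58788454,-3.851373154,14.36070847,low
P0001,0.8264461774,11.89066186,36.0860283,56.87600332,71.83986967,15.91202126,55.9278484,32.47040211,high
P0002,-0.9325599554,8.937437139,28.82343092,56.87109173,53.36874263,20.56224393,32.8064987,30.63403311,high
P0003,0.5042699336,1.369160492,7.475159185,41.63023489,27.37428397,0.266513588,27.10777038,7.122423184,low
P0004,-0.7340165807,4.559499921,24.60104034,60.09173034,24.64298544,12.02521678,12.61776866,15.83488223,low
P0005,-0.2407626221,7.781420266,7.595252779,16.89009953,38.52830971,2.263009677,36.26530004,12.61663618,low
P0006,-0.05745562205,16.67400479,47.75953158,62.6211585,44.69311291,33.45853091,11.234582,37.2667735,high
P0007,0.4320092541,8.02425464,22.94272373,47.23753047,51.82511229,28.28079682,23.54431546,35.08763823,high
P0008,-0.1863742393,-0.5004374398,6.222544308,22.77430982,28.41382036,2.349201476,26.06461889,9.592623862,low
P0009,0.6217481253,11.17209985,19.46385906,42.06112197,43.80494076,22.76827143,21.03666934,28.74869118,high
P0010,0.7089238945,11.66935829,33.58919758,62.86920861,51.3385499,20.85918387,30.47936603,29.88358632,high
P0011,-0.1205736913,5.53112456,4.732295057,3.734791925,26.77304898,6.019799258,20.75324973,12.32328858,low
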