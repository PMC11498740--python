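technique,replicate,value_mm
uCT,1,5.48
uCT,2,5.51
uCT,3,5.51
uCT,4,5.50
uCT,5,5.50
uCT,6,5.49
uCT,7,5.49
uCT,8,5.51
uCT,9,5.51
uCT,10,5.50
uCT,11,5.48
uCT,12,5.50
uCT,13,5.48
uCT,14,5.49
uCT,15,5.49
uCT,16,5.50
uCT,17,5.48
uCT,18,5.51
uCT,19,5.49
uCT,20,5.49
SL,1,5.60
SL,2,5.60
SL,3,5.62
SL,4,5.57
SL,5,5.60
SL,6,5.59
SL,7,5.58
SL,8,5.62
SL,9,5.61
SL,10,5.59
SL,11,5.59
SL,12,5.59
SL,13,5.58
SL,14,5.59
SL,15,5.57
SL,16,5.59
SL,17,5.58
SL,18,5.62
SL,19,5.59
SL,20,5.58
SfM,1,5.46
SfM,2,5.46
SfM,3,5.48
SfM,4,5.48
SfM,5,5.48
SfM,6,5.48
SfM,7,5.46
SfM,8,5.47
SfM,9,5.46
SfM,10,5.46
SfM,11,5.46
SfM,12,5.47
SfM,13,5.47
SfM,14,5.47
SfM,15,5.47
SfM,16,5.47
SfM,17,5.46
SfM,18,5.48
SfM,19,5.47
SfM,20,5.47
Sphere,1,5.50
Sphere,2,5.50
Sphere,3,5.52
Sphere,4,5.52
Sphere,5,5.51
Sphere,6,5.50
Sphere,7,5.51
Sphere,8,5.49
Sphere,9,5.52
Sphere,10,5.51
Sphere,11,5.51
Sphere,12,5.50
Sphere,13,5.55
Sphere,14,5.53
Sphere,15,5.51
Sphere,16,5.51
Sphere,17,5.52
Sphere,18,5.53
Sphere,19,5.54
Sphere,20,5.49
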