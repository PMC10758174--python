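item,factor1,factor2
Weak head,0.626,0.055
To rebel,0.578,0.079
Easy access,0.565,0.017
Influence of friends,0.538,0.060
Emotional problems,0.533,0.336
Going to parties/clubs,0.525,0.025
Desire for acceptance,0.511,0.123
Depression,0.499,0.218
Financial problems,0.491,0.277
Family history of addiction,0.487,0.076
Curiosity,0.482,0.113
Lonely or isolated,0.482,0.370
Stress,0.480,0.302
Addictive properties of alcohol/drugs,0.459,0.000
Lack of family structure/dialog,0.450,0.072
Predisposition to addiction,0.431,0.177
Believe that have control over use,0.406,0.326
Friends that use alcohol/drugs,0.353,-0.019
Family problems,0.372,0.110
Environment,0.350,0.123
A lot of money,0.133,0.201
Search for relief,0.286,0.270
Lack of god,0.250,0.272
Lack of knowledge,0.224,0.365
To escape reality,0.265,0.555
To feel better,0.118,0.575
To relax,-0.215,0.657
Search for pleasure,-0.127,0.690
Good sensation,0.024,0.708
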