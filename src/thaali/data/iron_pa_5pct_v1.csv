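# Tabulated probability of adequacy for iron in non-pregnant adults at 5%
# dietary bioavailability, v1.  Constructed by build_iron_table(): absorbed
# requirement ~ LogNormal(median 1.1 mg/d, sigma 0.35), dietary requirement
# = absorbed / 0.05; bounds at quantiles on a 0.02 probability grid, each
# interval carrying the midpoint probability.
upper_bound_mg,probability
10.7213,0.01
11.921,0.03
12.7671,0.05
13.4539,0.07
14.0483,0.09
14.5821,0.11
15.0734,0.13
15.5332,0.15
15.9692,0.17
16.3868,0.19
16.7899,0.21
17.1816,0.23
17.5644,0.25
17.9403,0.27
18.311,0.29
18.678,0.31
19.0426,0.33
19.406,0.35
19.7692,0.37
20.1332,0.39
20.4991,0.41
20.8677,0.43
21.2401,0.45
21.6172,0.47
22.0,0.49
22.3896,0.51
22.7871,0.53
23.1937,0.55
23.6108,0.57
24.0399,0.59
24.4826,0.61
24.9408,0.63
25.4167,0.65
25.9128,0.67
26.4322,0.69
26.9784,0.71
27.5558,0.73
28.1697,0.75
28.8269,0.77
29.536,0.79
30.3083,0.81
31.159,0.83
32.1096,0.85
33.1913,0.87
34.4526,0.89
35.9748,0.91
37.9099,0.93
40.6006,0.95
45.1439,0.97
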