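# Published multiple-linear-regression coefficients by FNU class:
# class_label	coefficient	std_err	ci_lower	ci_upper
Intercept	-60.90	11.61	-83.69	-38.11
0-0.49	61.34	11.66	38.45	84.24
0.5-0.99	61.57	11.61	38.77	84.37
1-2.49	62.48	11.61	39.69	85.28
2.5-4.99	65.53	11.62	42.72	88.35
5-9.99	67.76	11.62	44.95	90.58
10-14.99	73.91	11.63	51.08	96.74
15-20.99	77.63	11.63	54.78	100.48
21-28.99	85.64	11.66	62.75	108.53
29-36.99	93.29	11.66	70.40	116.17
37-44.99	99.40	11.60	76.61	122.19
45-55	114.32	11.76	91.24	137.41
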