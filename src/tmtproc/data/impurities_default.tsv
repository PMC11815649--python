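# tmtproc default TMTpro impurity table v1
# fractions of each tag's region signal appearing at nominal-mass offsets -2..+2
tag_name	region	offset	fraction
126	reporter	0	0.9821
126	reporter	1	0.0164
126	reporter	2	0.0015
126	complement	-2	0.0028
126	complement	-1	0.028
126	complement	0	0.9577
126	complement	1	0.01
126	complement	2	0.0015
127N	reporter	-1	0.0035
127N	reporter	0	0.9786
127N	reporter	1	0.0164
127N	reporter	2	0.0015
127N	complement	-2	0.0024
127N	complement	-1	0.0245
127N	complement	0	0.9616
127N	complement	1	0.01
127N	complement	2	0.0015
127C	reporter	-1	0.0035
127C	reporter	0	0.9794
127C	reporter	1	0.0156
127C	reporter	2	0.0015
127C	complement	-2	0.0024
127C	complement	-1	0.0245
127C	complement	0	0.9608
127C	complement	1	0.0108
127C	complement	2	0.0015
128N	reporter	-2	0.0004
128N	reporter	-1	0.007
128N	reporter	0	0.9755
128N	reporter	1	0.0156
128N	reporter	2	0.0015
128N	complement	-2	0.002
128N	complement	-1	0.021
128N	complement	0	0.9647
128N	complement	1	0.0108
128N	complement	2	0.0015
128C	reporter	-2	0.0004
128C	reporter	-1	0.007
128C	reporter	0	0.9763
128C	reporter	1	0.0148
128C	reporter	2	0.0015
128C	complement	-2	0.002
128C	complement	-1	0.021
128C	complement	0	0.9639
128C	complement	1	0.0116
128C	complement	2	0.0015
129N	reporter	-2	0.0008
129N	reporter	-1	0.0105
129N	reporter	0	0.9724
129N	reporter	1	0.0148
129N	reporter	2	0.0015
129N	complement	-2	0.0016
129N	complement	-1	0.0175
129N	complement	0	0.9678
129N	complement	1	0.0116
129N	complement	2	0.0015
129C	reporter	-2	0.0008
129C	reporter	-1	0.0105
129C	reporter	0	0.9732
129C	reporter	1	0.014
129C	reporter	2	0.0015
129C	complement	-2	0.0016
129C	complement	-1	0.0175
129C	complement	0	0.967
129C	complement	1	0.0124
129C	complement	2	0.0015
130N	reporter	-2	0.0012
130N	reporter	-1	0.014
130N	reporter	0	0.9693
130N	reporter	1	0.014
130N	reporter	2	0.0015
130N	complement	-2	0.0012
130N	complement	-1	0.014
130N	complement	0	0.9709
130N	complement	1	0.0124
130N	complement	2	0.0015
130C	reporter	-2	0.0012
130C	reporter	-1	0.014
130C	reporter	0	0.9701
130C	reporter	1	0.0132
130C	reporter	2	0.0015
130C	complement	-2	0.0012
130C	complement	-1	0.014
130C	complement	0	0.9701
130C	complement	1	0.0132
130C	complement	2	0.0015
131N	reporter	-2	0.0016
131N	reporter	-1	0.0175
131N	reporter	0	0.9662
131N	reporter	1	0.0132
131N	reporter	2	0.0015
131N	complement	-2	0.0008
131N	complement	-1	0.0105
131N	complement	0	0.974
131N	complement	1	0.0132
131N	complement	2	0.0015
131C	reporter	-2	0.0016
131C	reporter	-1	0.0175
131C	reporter	0	0.967
131C	reporter	1	0.0124
131C	reporter	2	0.0015
131C	complement	-2	0.0008
131C	complement	-1	0.0105
131C	complement	0	0.9732
131C	complement	1	0.014
131C	complement	2	0.0015
132N	reporter	-2	0.002
132N	reporter	-1	0.021
132N	reporter	0	0.9631
132N	reporter	1	0.0124
132N	reporter	2	0.0015
132N	complement	-2	0.0004
132N	complement	-1	0.007
132N	complement	0	0.9771
132N	complement	1	0.014
132N	complement	2	0.0015
132C	reporter	-2	0.002
132C	reporter	-1	0.021
132C	reporter	0	0.9639
132C	reporter	1	0.0116
132C	reporter	2	0.0015
132C	complement	-2	0.0004
132C	complement	-1	0.007
132C	complement	0	0.9763
132C	complement	1	0.0148
132C	complement	2	0.0015
133N	reporter	-2	0.0024
133N	reporter	-1	0.0245
133N	reporter	0	0.96
133N	reporter	1	0.0116
133N	reporter	2	0.0015
133N	complement	-1	0.0035
133N	complement	0	0.981
133N	complement	1	0.014
133N	complement	2	0.0015
133C	reporter	-2	0.0024
133C	reporter	-1	0.0245
133C	reporter	0	0.9608
133C	reporter	1	0.0108
133C	reporter	2	0.0015
133C	complement	-1	0.0035
133C	complement	0	0.9802
133C	complement	1	0.0148
133C	complement	2	0.0015
134N	reporter	-2	0.0028
134N	reporter	-1	0.028
134N	reporter	0	0.9569
134N	reporter	1	0.0108
134N	reporter	2	0.0015
134N	complement	0	0.9837
134N	complement	1	0.0148
134N	complement	2	0.0015
134C	reporter	-2	0.0028
134C	reporter	-1	0.028
134C	reporter	0	0.9577
134C	reporter	1	0.01
134C	reporter	2	0.0015
134C	complement	-1	0.0035
134C	complement	0	0.9802
134C	complement	1	0.0148
134C	complement	2	0.0015
135N	reporter	-2	0.0032
135N	reporter	-1	0.0315
135N	reporter	0	0.9538
135N	reporter	1	0.01
135N	reporter	2	0.0015
135N	complement	0	0.9837
135N	complement	1	0.0148
135N	complement	2	0.0015
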