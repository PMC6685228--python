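G000001
G000002
G000003
G000004
G000005
G000006
G000007
G000008
G000009
G000010
G000011
G000012
G000013
G000014
G000015
G000016
G000017
G000018
G000019
G000020
G000021
G000022
G000023
G000024
G000025
G000026
G000027
G000028
G000029
G000030
G000031
G000032
G000033
G000034
G000035
G000036
G000037
G000038
G000039
G000040
G000041
G000042
G000043
G000044
G000045
G000046
G000047
G000048
G000049
G000050
G000051
G000052
G000053
G000054
G000055
G000056
G000057
G000058
G000059
G000060
G000061
G000062
G000063
G000064
G000065
G000066
G000067
G000068
G000069
G000070
G000071
G000072
G000073
G000074
G000075
G000076
G000077
G000078
G000079
G000080
G000081
G000082
G000083
G000084
G000085
G000086
G000087
G000088
G000089
G000090
G000091
G000092
G000093
G000094
G000095
G000096
G000097
G000098
G000099
G000100
G000101
G000102
G000103
G000104
G000105
G000106
G000107
G000108
G000109
G000110
G000111
G000112
G000113
G000114
G000115
G000116
G000117
G000118
G000119
G000120
G000121
G000122
G000123
G000124
G000125
G000126
G000127
G000128
G000129
G000130
G000131
G000132
G000133
G000134
G000135
G000136
G000137
G000138
G000139
G000140
G000141
G000142
G000143
G000144
G000145
G000146
G000147
G000148
G000149
G000150
G000151
G000152
G000153
G000154
G000155
G000156
G000157
G000158
G000159
G000160
G000161
G000162
G000163
G000164
G000165
G000166
G000167
G000168
G000169
G000170
G000171
G000172
G000173
G000174
G000175
G000176
G000177
G000178
G000179
G000180
G000181
G000182
G000183
G000184
G000185
G000186
G000187
G000188
G000189
G000190
G000191
G000192
G000193
G000194
G000195
G000196
G000197
G000198
G000199
G000200
G000201
G000202
G000203
G000204
G000205
G000206
G000207
G000208
G000209
G000210
G000211
G000212
G000213
G000214
G000215
G000216
G000217
G000218
G000219
G000220
G000221
G000222
G000223
G000224
G000225
G000226
G000227
G000228
G000229
G000230
G000231
G000232
G000233
G000234
G000235
G000236
G000237
G000238
G000239
G000240
G000241
G000242
G000243
G000244
G000245
G000246
G000247
G000248
G000249
G000250
G000251
G000252
G000253
G000254
G000255
G000256
G000257
G000258
G000259
G000260
G000261
G000262
G000263
G000264
G000265
G000266
G000267
G000268
G000269
G000270
G000271
G000272
G000273
G000274
G000275
G000276
G000277
G000278
G000279
G000280
G000281
G000282
G000283
G000284
G000285
G000286
G000287
G000288
G000289
G000290
G000291
G000292
G000293
G000294
G000295
G000296
G000297
G000298
G000299
G000300
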