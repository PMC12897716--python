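bead_i	bead_j
0	410
1	2
2	3
3	410
4	5
5	6
6	411
7	411
8	9
9	10
10	11
11	412
12	13
12	410
13	14
14	15
15	16
16	17
17	18
18	19
19	412
20	21
20	410
21	22
22	23
23	24
24	25
25	26
26	27
27	413
28	29
29	30
30	31
31	414
32	33
33	34
34	35
35	413
36	37
36	411
37	38
38	39
39	40
40	41
41	42
42	43
43	414
44	45
44	411
45	46
46	47
47	48
48	49
49	50
50	51
51	415
52	53
53	54
54	55
55	415
56	416
57	417
58	59
58	412
59	60
60	61
61	62
62	63
63	64
64	65
65	416
66	67
66	412
67	68
68	69
69	70
70	71
71	72
72	73
73	418
74	75
74	413
75	76
76	77
77	78
78	79
79	80
80	81
81	417
82	83
82	413
83	84
84	85
85	86
86	87
87	88
88	89
89	419
90	91
90	414
91	92
92	93
93	94
94	95
95	96
96	97
97	418
98	99
98	414
99	100
100	101
101	102
102	103
103	104
104	105
105	420
106	107
106	415
107	108
108	109
109	110
110	111
111	112
112	113
113	419
114	115
114	415
115	116
116	117
117	118
118	119
119	120
120	121
121	421
122	420
123	421
124	125
124	416
125	126
127	128
127	416
128	129
129	130
130	131
131	132
132	133
133	134
134	422
135	136
136	137
137	138
138	423
139	140
139	417
140	141
141	142
142	143
143	144
144	145
145	146
146	422
147	148
147	417
148	149
150	151
150	418
151	152
152	153
153	154
154	155
155	156
156	157
157	423
158	159
158	418
159	160
160	161
161	162
162	163
163	164
164	165
165	424
166	167
166	419
167	168
168	169
169	170
170	171
171	172
172	173
173	424
174	175
174	419
175	176
176	177
177	178
178	179
179	180
180	181
181	425
182	183
182	420
183	184
185	186
185	420
186	187
187	188
188	189
189	190
190	191
191	192
192	426
193	194
194	195
195	196
196	425
197	198
197	421
198	199
199	200
200	201
201	202
202	203
203	204
204	426
205	206
205	421
206	207
208	209
209	210
210	427
211	212
211	422
212	213
213	214
215	216
215	422
216	217
217	218
218	219
219	220
220	221
221	222
222	428
223	224
223	423
224	225
225	226
226	227
227	228
228	229
229	230
230	427
231	232
231	423
232	233
233	234
234	235
235	236
236	237
237	238
238	429
239	240
240	241
241	430
242	243
242	424
243	244
244	245
245	246
246	247
247	248
248	249
249	428
250	251
250	424
251	252
252	253
253	254
254	255
255	256
256	257
257	431
258	259
259	260
260	429
261	262
261	425
262	263
263	264
264	265
265	266
266	267
267	268
268	430
269	270
269	425
270	271
271	272
272	273
273	274
274	275
275	276
276	432
277	278
277	426
278	279
279	280
280	281
281	282
282	283
283	284
284	431
285	286
285	426
286	287
287	288
289	290
290	291
291	432
292	427
293	294
293	427
294	295
295	296
296	297
297	298
298	299
299	300
300	433
301	302
301	428
302	303
303	304
304	305
305	306
306	307
307	308
308	433
309	310
309	428
310	311
311	312
312	313
313	314
314	315
315	316
316	434
317	429
318	319
318	429
319	320
320	321
321	322
322	323
323	324
324	325
325	435
326	327
326	430
327	328
328	329
329	330
330	331
331	332
332	333
333	434
334	430
335	336
335	431
336	337
337	338
338	339
339	340
340	341
341	342
342	435
343	344
343	431
344	345
345	346
346	347
347	348
348	349
349	350
350	436
351	352
351	432
352	353
353	354
354	355
355	356
356	357
357	358
358	436
359	432
360	361
360	433
361	362
363	364
363	433
364	365
365	366
366	367
367	368
368	369
369	370
370	437
371	372
371	434
372	373
374	375
374	434
375	376
376	377
377	378
378	379
379	380
380	381
381	438
382	383
382	435
383	384
384	385
385	386
386	387
387	388
388	389
389	437
390	391
390	435
391	392
393	394
393	436
394	395
395	396
396	397
397	398
398	399
399	400
400	438
401	402
401	436
402	403
404	405
404	437
405	406
407	408
407	438
408	409
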