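node_id,name,hemisphere,region_class
0,Left-Bankssts,left,temporal
1,Left-CaudalAnteriorCingulate,left,cingulate
2,Left-CaudalMiddleFrontal,left,frontal
3,Left-Cuneus,left,occipital
4,Left-Entorhinal,left,temporal
5,Left-Fusiform,left,temporal
6,Left-InferiorParietal,left,parietal
7,Left-InferiorTemporal,left,temporal
8,Left-IsthmusCingulate,left,cingulate
9,Left-LateralOccipital,left,occipital
10,Left-LateralOrbitofrontal,left,frontal
11,Left-Lingual,left,occipital
12,Left-MedialOrbitofrontal,left,frontal
13,Left-MiddleTemporal,left,temporal
14,Left-Parahippocampal,left,temporal
15,Left-Paracentral,left,frontal
16,Left-ParsOpercularis,left,frontal
17,Left-ParsOrbitalis,left,frontal
18,Left-ParsTriangularis,left,frontal
19,Left-Pericalcarine,left,occipital
20,Left-Postcentral,left,parietal
21,Left-PosteriorCingulate,left,cingulate
22,Left-Precentral,left,frontal
23,Left-Precuneus,left,parietal
24,Left-RostralAnteriorCingulate,left,cingulate
25,Left-RostralMiddleFrontal,left,frontal
26,Left-SuperiorFrontal,left,frontal
27,Left-SuperiorParietal,left,parietal
28,Left-SuperiorTemporal,left,temporal
29,Left-Supramarginal,left,parietal
30,Left-FrontalPole,left,frontal
31,Left-TemporalPole,left,temporal
32,Left-TransverseTemporal,left,temporal
33,Left-Insula,left,insula
34,Left-Thalamus,left,diencephalon
35,Left-Caudate,left,basal_ganglia
36,Left-Putamen,left,basal_ganglia
37,Left-Pallidum,left,basal_ganglia
38,Left-Hippocampus,left,temporal
39,Left-Amygdala,left,temporal
40,Left-Accumbens,left,basal_ganglia
41,Left-VentralDC,left,diencephalon
42,Left-Cerebellum,left,cerebellum
43,Right-Bankssts,right,temporal
44,Right-CaudalAnteriorCingulate,right,cingulate
45,Right-CaudalMiddleFrontal,right,frontal
46,Right-Cuneus,right,occipital
47,Right-Entorhinal,right,temporal
48,Right-Fusiform,right,temporal
49,Right-InferiorParietal,right,parietal
50,Right-InferiorTemporal,right,temporal
51,Right-IsthmusCingulate,right,cingulate
52,Right-LateralOccipital,right,occipital
53,Right-LateralOrbitofrontal,right,frontal
54,Right-Lingual,right,occipital
55,Right-MedialOrbitofrontal,right,frontal
56,Right-MiddleTemporal,right,temporal
57,Right-Parahippocampal,right,temporal
58,Right-Paracentral,right,frontal
59,Right-ParsOpercularis,right,frontal
60,Right-ParsOrbitalis,right,frontal
61,Right-ParsTriangularis,right,frontal
62,Right-Pericalcarine,right,occipital
63,Right-Postcentral,right,parietal
64,Right-PosteriorCingulate,right,cingulate
65,Right-Precentral,right,frontal
66,Right-Precuneus,right,parietal
67,Right-RostralAnteriorCingulate,right,cingulate
68,Right-RostralMiddleFrontal,right,frontal
69,Right-SuperiorFrontal,right,frontal
70,Right-SuperiorParietal,right,parietal
71,Right-SuperiorTemporal,right,temporal
72,Right-Supramarginal,right,parietal
73,Right-FrontalPole,right,frontal
74,Right-TemporalPole,right,temporal
75,Right-TransverseTemporal,right,temporal
76,Right-Insula,right,insula
77,Right-Thalamus,right,diencephalon
78,Right-Caudate,right,basal_ganglia
79,Right-Putamen,right,basal_ganglia
80,Right-Pallidum,right,basal_ganglia
81,Right-Hippocampus,right,temporal
82,Right-Amygdala,right,temporal
83,Right-Accumbens,right,basal_ganglia
84,Right-VentralDC,right,diencephalon
85,Right-Cerebellum,right,cerebellum
86,Brainstem,midline,brainstem
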