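index,name,lobe,hemisphere,x,y,z
0,Precentral_L,Frontal,L,-39,-6,51
1,Precentral_R,Frontal,R,39,-6,51
2,Frontal_Sup_L,Frontal,L,-22,31,44
3,Frontal_Sup_R,Frontal,R,22,31,44
4,Frontal_Sup_Orb_L,Frontal,L,-17,47,-13
5,Frontal_Sup_Orb_R,Frontal,R,17,47,-13
6,Frontal_Mid_L,Frontal,L,-34,33,35
7,Frontal_Mid_R,Frontal,R,34,33,35
8,Frontal_Mid_Orb_L,Frontal,L,-31,50,-10
9,Frontal_Mid_Orb_R,Frontal,R,31,50,-10
10,Frontal_Inf_Oper_L,Frontal,L,-49,15,21
11,Frontal_Inf_Oper_R,Frontal,R,49,15,21
12,Frontal_Inf_Tri_L,Frontal,L,-47,30,14
13,Frontal_Inf_Tri_R,Frontal,R,47,30,14
14,Frontal_Inf_Orb_L,Frontal,L,-37,31,-12
15,Frontal_Inf_Orb_R,Frontal,R,37,31,-12
16,Rolandic_Oper_L,Frontal,L,-50,-8,15
17,Rolandic_Oper_R,Frontal,R,50,-8,15
18,Supp_Motor_Area_L,Frontal,L,-6,5,61
19,Supp_Motor_Area_R,Frontal,R,6,5,61
20,Olfactory_L,Frontal,L,-9,15,-11
21,Olfactory_R,Frontal,R,9,15,-11
22,Frontal_Sup_Medial_L,Frontal,L,-6,49,31
23,Frontal_Sup_Medial_R,Frontal,R,6,49,31
24,Frontal_Med_Orb_L,Frontal,L,-6,54,-7
25,Frontal_Med_Orb_R,Frontal,R,6,54,-7
26,Rectus_L,Frontal,L,-6,37,-18
27,Rectus_R,Frontal,R,6,37,-18
28,Insula_L,Insula,L,-36,7,3
29,Insula_R,Insula,R,36,7,3
30,Cingulum_Ant_L,Limbic,L,-5,35,14
31,Cingulum_Ant_R,Limbic,R,5,35,14
32,Cingulum_Mid_L,Limbic,L,-6,-15,42
33,Cingulum_Mid_R,Limbic,R,6,-15,42
34,Cingulum_Post_L,Limbic,L,-6,-43,25
35,Cingulum_Post_R,Limbic,R,6,-43,25
36,Hippocampus_L,Medial-Temporal,L,-26,-21,-10
37,Hippocampus_R,Medial-Temporal,R,26,-21,-10
38,ParaHippocampal_L,Medial-Temporal,L,-24,-15,-20
39,ParaHippocampal_R,Medial-Temporal,R,24,-15,-20
40,Amygdala_L,Medial-Temporal,L,-24,-1,-17
41,Amygdala_R,Medial-Temporal,R,24,-1,-17
42,Calcarine_L,Occipital,L,-9,-79,6
43,Calcarine_R,Occipital,R,9,-79,6
44,Cuneus_L,Occipital,L,-7,-80,27
45,Cuneus_R,Occipital,R,7,-80,27
46,Lingual_L,Occipital,L,-15,-68,-5
47,Lingual_R,Occipital,R,15,-68,-5
48,Occipital_Sup_L,Occipital,L,-18,-84,28
49,Occipital_Sup_R,Occipital,R,18,-84,28
50,Occipital_Mid_L,Occipital,L,-33,-81,16
51,Occipital_Mid_R,Occipital,R,33,-81,16
52,Occipital_Inf_L,Occipital,L,-37,-82,-8
53,Occipital_Inf_R,Occipital,R,37,-82,-8
54,Fusiform_L,Temporal,L,-32,-40,-20
55,Fusiform_R,Temporal,R,32,-40,-20
56,Postcentral_L,Parietal,L,-42,-23,49
57,Postcentral_R,Parietal,R,42,-23,49
58,Parietal_Sup_L,Parietal,L,-24,-60,59
59,Parietal_Sup_R,Parietal,R,24,-60,59
60,Parietal_Inf_L,Parietal,L,-43,-46,47
61,Parietal_Inf_R,Parietal,R,43,-46,47
62,SupraMarginal_L,Parietal,L,-56,-32,34
63,SupraMarginal_R,Parietal,R,56,-32,34
64,Angular_L,Parietal,L,-45,-60,39
65,Angular_R,Parietal,R,45,-60,39
66,Precuneus_L,Parietal,L,-8,-56,48
67,Precuneus_R,Parietal,R,8,-56,48
68,Paracentral_Lobule_L,Frontal,L,-6,-25,61
69,Paracentral_Lobule_R,Frontal,R,6,-25,61
70,Caudate_L,Subcortical,L,-13,11,9
71,Caudate_R,Subcortical,R,13,11,9
72,Putamen_L,Subcortical,L,-25,4,2
73,Putamen_R,Subcortical,R,25,4,2
74,Pallidum_L,Subcortical,L,-19,0,0
75,Pallidum_R,Subcortical,R,19,0,0
76,Thalamus_L,Subcortical,L,-12,-18,8
77,Thalamus_R,Subcortical,R,12,-18,8
78,Heschl_L,Temporal,L,-43,-19,10
79,Heschl_R,Temporal,R,43,-19,10
80,Temporal_Sup_L,Temporal,L,-55,-21,7
81,Temporal_Sup_R,Temporal,R,55,-21,7
82,Temporal_Pole_Sup_L,Temporal,L,-40,15,-20
83,Temporal_Pole_Sup_R,Temporal,R,40,15,-20
84,Temporal_Mid_L,Temporal,L,-56,-34,-2
85,Temporal_Mid_R,Temporal,R,56,-34,-2
86,Temporal_Pole_Mid_L,Temporal,L,-40,15,-32
87,Temporal_Pole_Mid_R,Temporal,R,40,15,-32
88,Temporal_Inf_L,Temporal,L,-51,-28,-23
89,Temporal_Inf_R,Temporal,R,51,-28,-23
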