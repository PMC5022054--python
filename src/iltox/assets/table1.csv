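NO,system,R2,SE,z,alpha,beta,N
1,Leukemia rat cell (A),0.73,0.47,0.00,1.00,0.00,199
2,S. vacuolatus (A),0.75,0.70,1.45,1.12,-0.18,48
3,V. fischeri (A),0.69,0.35,0.23,1.38,-0.47,108
4,D. magna (B & C),0.81,0.42,1.63,1.02,-0.04,70
5,PA of P. subcapitata (A),0.68,0.33,-0.73,1.43,0.29,8
6,MCF-7 (C),0.81,0.29,-0.05,1.80,-0.38,16
7,Hela cell with FBS for 24 h (A),0.67,0.43,-0.34,0.95,-0.03,23
8,Hela cell without FBS for 24 h (A),0.85,0.30,-0.02,1.40,0.12,17
9,Hela cell for 48 h (A),0.76,0.33,-0.26,0.78,-0.08,38
10,GR of A. hydrophila (A),0.86,0.32,-1.00,1.07,0.04,25
11,GR of E. coli (A),0.85,0.32,-0.98,1.08,0.04,25
12,GR of L. monocytogenes (A),0.86,0.32,-1.02,1.06,0.03,25
13,GR of S. aureus (A),0.85,0.33,-0.97,1.07,0.35,25
14,E. coli (E),0.87,0.49,-0.88,0.90,-0.15,91
15,E. coli (F),0.93,0.42,-1.13,0.90,-0.06,45
16,M. luteus (E),0.80,0.43,-0.55,1.00,0.00,46
17,M. luteus (F),0.87,0.39,-1.17,0.85,0.10,33
18,S. epidermidis (E),0.82,0.46,-0.88,0.83,0.10,36
19,S. epidermidis (F),0.84,0.33,-1.45,0.76,0.08,32
20,S. aureus (E),0.93,0.41,-1.06,1.01,-0.01,86
21,S. aureus (F),0.96,0.36,-1.36,0.90,-0.06,49
22,S. aureus MRSA (E),0.78,0.25,-1.18,1.17,-0.07,23
23,S. aureus MRSA (F),0.70,0.23,-1.53,1.06,-0.02,19
24,E. hirae (E),0.91,0.33,-1.10,1.07,-0.03,43
25,E. hirae (F),0.72,0.22,-1.53,1.05,-0.01,19
26,P. vulgaris (E),0.68,0.36,-1.15,0.68,0.11,39
27,K. pneumoniae (E),0.68,0.38,-0.83,0.57,0.20,31
28,K. pneumoniae (F),0.80,0.23,-1.11,0.75,0.09,23
29,C. albicans (E),0.81,0.47,-1.25,1.00,0.00,57
30,C. albicans (F),0.68,0.30,-1.37,0.86,0.02,24
31,R. rubra (E),0.64,0.39,-0.84,0.76,0.15,41
32,R. rubra (F),0.59,0.34,-1.31,0.75,0.06,24
33,S. enteritidis (E),0.67,0.11,-0.79,2.22,2.15,21
34,S. enteritidis (F),0.72,0.10,-0.92,2.31,2.48,21
35,L. monocytogenes (E),0.72,0.10,-1.06,2.55,3.14,21
36,L. monocytogenes (F),0.64,0.11,-1.12,2.32,2.76,21
37,E. faecalis (E),0.95,0.30,-1.14,1.09,-0.01,21
38,C. glabrata (E),0.92,0.39,-1.43,1.01,-0.06,19
39,C. tropicalis (E),0.90,0.45,-1.52,0.90,-0.15,19
40,S. cerevisiae (E),0.86,0.51,-1.25,0.92,-0.11,21
41,S. cerevisiae JG (E),0.88,0.47,-1.24,0.96,-0.09,20
42,S. cerevisiae JGCDR1 (E),0.92,0.38,-1.31,0.94,-1.05,20
43,G. candidum (E),0.88,0.47,-1.14,1.13,0.00,20
44,R. mucilaginosa (E),0.93,0.41,-1.17,1.06,-0.03,21
45,Acetylcholinesterase (A),0.07,0.65,0.82,0.19,0.71,226
46,L. minor (A),0.34,0.57,0.52,0.95,0.02,10
47,P. subcapitata (A),0.17,0.67,0.45,0.58,0.13,26
48,P. vulgaris (F),0.31,0.31,-1.74,0.24,0.06,27
49,P. aeruginosa (E),0.32,0.32,-1.77,0.41,-0.11,34
50,P. aeruginosa (F),0.01,0.20,-1.90,-0.04,-0.38,15
51,S. marcescens (E),0.19,0.41,-1.41,0.31,0.08,28
52,S. marcescens (F),0.11,0.33,-1.72,0.24,-0.11,22
53,GR of B. paxillifer (A),0.82,0.22,2.30,0.65,0.79,10
54,GR of G. amphibium (A),0.98,0.16,2.81,1.43,-1.19,10
55,GR of C. vulgaris (A),0.92,0.32,0.46,1.56,-0.23,10
56,GR of O. submarina (A),0.95,0.22,0.10,1.38,-0.02,10
57,GR of S. marinoi (A),0.88,0.32,2.73,1.15,-0.41,10
58,GR of C. meneghiniana (A),0.91,0.22,2.41,0.97,0.08,10
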