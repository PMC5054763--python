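index,region,x_mm,y_mm,z_mm
0,jawline,-75.0,0.0,60.0
1,jawline,-73.0,16.0,55.0
2,jawline,-70.0,32.0,48.0
3,jawline,-65.0,47.0,39.0
4,jawline,-56.0,61.0,28.0
5,jawline,-44.0,73.0,16.0
6,jawline,-30.0,82.0,6.0
7,jawline,-15.5,89.0,-1.0
8,jawline,0.0,91.5,-4.0
9,jawline,15.5,89.0,-1.0
10,jawline,30.0,82.0,6.0
11,jawline,44.0,73.0,16.0
12,jawline,56.0,61.0,28.0
13,jawline,65.0,47.0,39.0
14,jawline,70.0,32.0,48.0
15,jawline,73.0,16.0,55.0
16,jawline,75.0,0.0,60.0
17,eyebrow_right,-57.0,-9.0,6.0
18,eyebrow_right,-48.0,-13.0,0.0
19,eyebrow_right,-37.5,-15.0,-3.0
20,eyebrow_right,-27.0,-13.5,-4.0
21,eyebrow_right,-17.5,-10.5,-4.5
22,eyebrow_left,17.5,-10.5,-4.5
23,eyebrow_left,27.0,-13.5,-4.0
24,eyebrow_left,37.5,-15.0,-3.0
25,eyebrow_left,48.0,-13.0,0.0
26,eyebrow_left,57.0,-9.0,6.0
27,nose,0.0,-5.0,-10.0
28,nose,0.0,7.0,-16.0
29,nose,0.0,17.5,-22.0
30,nose,0.0,27.5,-28.0
31,nose,-11.0,34.0,-14.0
32,nose,-5.5,36.0,-16.5
33,nose,0.0,37.0,-18.0
34,nose,5.5,36.0,-16.5
35,nose,11.0,34.0,-14.0
36,eye_right,-44.5,0.0,2.0
37,eye_right,-38.5,-4.0,-1.0
38,eye_right,-26.5,-4.0,-1.0
39,eye_right,-20.5,0.0,2.0
40,eye_right,-26.5,4.0,-1.0
41,eye_right,-38.5,4.0,-1.0
42,eye_left,20.5,0.0,2.0
43,eye_left,26.5,-4.0,-1.0
44,eye_left,38.5,-4.0,-1.0
45,eye_left,44.5,0.0,2.0
46,eye_left,38.5,4.0,-1.0
47,eye_left,26.5,4.0,-1.0
48,lips,-26.0,60.0,-6.0
49,lips,-17.0,55.0,-10.5
50,lips,-6.5,52.5,-13.0
51,lips,0.0,52.0,-13.5
52,lips,6.5,52.5,-13.0
53,lips,17.0,55.0,-10.5
54,lips,26.0,60.0,-6.0
55,lips,17.0,66.5,-10.0
56,lips,6.5,70.0,-12.0
57,lips,0.0,70.5,-12.5
58,lips,-6.5,70.0,-12.0
59,lips,-17.0,66.5,-10.0
60,lips,-20.0,60.0,-8.0
61,lips,-6.5,57.5,-12.0
62,lips,0.0,57.0,-12.5
63,lips,6.5,57.5,-12.0
64,lips,20.0,60.0,-8.0
65,lips,6.5,63.5,-11.5
66,lips,0.0,64.0,-12.0
67,lips,-6.5,63.5,-11.5
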