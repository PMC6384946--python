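run_id,dataset_tag,split,pH_i,dpH_dt,phi_i,dphi_dt,phi_f,pH_f
1A,A,train,2.8,0,0.20,0.06,0.5,
2A,A,val,2.8,0,0.20,0.03,0.5,
3A,A,train,2.8,0,0.20,0.015,0.5,
4A,A,test,3.3,0,0.20,0.03,0.5,
5A,A,test,3.3,0,0.20,0.02,0.5,
6A,A,train,3.3,0,0.20,0.015,0.5,
7A,A,test,3.3,0,0.20,0.01,0.5,
8A,A,train,3.82,0,0.20,0.06,0.5,
9A,A,test,3.82,0,0.20,0.018,0.5,
10A,A,train,3.82,0,0.20,0.012,0.5,
11A,A,train,4.2,0,0.20,0.03,0.5,
12A,A,train,4.2,0,0.20,0.015,0.5,
13A,A,val,4.2,0,0.20,0.01,0.5,
14A,A,val,5.85,0,0.20,0.015,0.5,
15A,A,train,5.85,0,0.20,0.01,0.5,
16A,A,test,5.85,0,0.20,0.0075,0.5,
17A,A,train,7.8,0,0.20,0.015,0.5,
18A,A,test,7.8,0,0.20,0.01,0.5,
19A,A,train,7.8,0,0.20,0.0075,0.5,
1B,B,train,2.8,0.79,0.35,0,,10.7
2B,B,val,2.8,0.527,0.35,0,,10.7
3B,B,test,2.8,0.395,0.35,0,,10.7
4B,B,train,2.8,0.263,0.35,0,,10.7
5B,B,val,2.8,0.527,0.25,0,,10.7
6B,B,train,2.8,0.527,0.27,0,,10.7
7B,B,test,2.8,0.527,0.30,0,,10.7
8B,B,train,2.8,0.263,0.25,0,,10.7
9B,B,test,2.8,0.263,0.27,0,,10.7
10B,B,train,2.8,0.263,0.30,0,,10.7
11B,B,train,3.2,0.580,0.25,0,,9.0
12B,B,train,3.2,0.387,0.25,0,,9.0
13B,B,val,3.2,0.290,0.25,0,,9.0
14B,B,train,3.2,0.193,0.25,0,,9.0
15B,B,train,3.2,0.387,0.27,0,,9.0
16B,B,test,3.2,0.387,0.30,0,,9.0
17B,B,test,3.2,0.387,0.35,0,,9.0
18B,B,train,3.2,0.290,0.30,0,,9.0
19B,B,val,3.2,0.290,0.35,0,,9.0
20B,B,test,3.2,0.193,0.27,0,,9.0
21B,B,train,3.2,0.193,0.30,0,,9.0
22B,B,train,3.2,0.193,0.35,0,,9.0
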