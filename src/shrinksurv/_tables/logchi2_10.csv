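r,w,m,v
1,0.060620177956884999,1.4133188893190129,0.2014230082255383
2,0.10217648368910666,0.7826416708590076,0.21335875545720823
3,0.11263502117971168,0.20623081644207661,0.31848326879169148
4,0.1152548506405433,-0.14963889872843514,0.43454666692692467
5,0.11849162956441915,-0.62090596487841443,0.55464164962745288
6,0.13743756391351894,-1.2809665634015082,0.68494171802907899
7,0.18767348854010341,-2.2411335046790888,1.3959501771684153
8,0.12253454101567963,-3.8819760071927032,2.9696964369925634
9,0.038352027185924988,-6.4698795952600703,6.1538826550428016
10,0.004824216314107236,-9.9399824513797412,15.223356585054935
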