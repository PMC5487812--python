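Date,Time,Winner,Loser,K,Outcome
2003-08-10,15:34,ZF,TK,100,1
2003-10-13,08:56,DN,ZF,200,1
2003-10-16,08:44,ZF,TK,200,1
2003-10-24,09:11,ZF,MA,275,1
2003-10-28,11:09,ZF,NK,200,1
2003-10-28,11:11,DN,ZF,200,1
2003-10-28,11:12,ZF,TK,200,1
2003-10-28,12:05,NK,TK,200,1
2003-10-28,12:36,NK,TK,100,1
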