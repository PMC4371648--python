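pair,word,word_class,tasa_logfreq,letters,phonemes,elp_latency,exp_latency
1,blast,contrastive,0.96,5,5,562,859
1,blame,non_contrastive,1.11,5,4,576,829
2,boast,contrastive,0.31,5,4,574,1125
2,bumps,non_contrastive,0.99,5,5,572,878
3,bound,contrastive,0.99,5,4,567,902
3,brush,non_contrastive,1.68,5,4,558,978
4,build,contrastive,1.98,5,4,622,972
4,beach,non_contrastive,1.92,5,3,624,926
5,burst,contrastive,1.43,5,4,645,971
5,banks,non_contrastive,1.26,5,5,605,894
6,coast,contrastive,1.57,5,4,636,1070
6,crack,non_contrastive,1.49,5,4,620,773
7,drift,contrastive,0.68,5,5,618,744
7,drank,non_contrastive,1.41,5,5,640,914
8,end,contrastive,2.57,3,3,586,730
8,air,non_contrastive,2.69,3,2,588,726
9,ghost,contrastive,1.54,5,4,556,891
9,goose,non_contrastive,1.24,5,3,628,1002
10,hind,contrastive,0.91,4,4,615,757
10,hush,non_contrastive,0.80,4,3,591,737
11,hound,contrastive,0.87,5,4,582,872
11,hatch,non_contrastive,1.12,5,3,603,803
12,lend,contrastive,0.92,4,4,625,885
12,lawn,non_contrastive,1.34,4,3,583,1019
13,loft,contrastive,0.56,4,4,564,892
13,loom,non_contrastive,0.78,4,3,605,879
14,old,contrastive,3.01,3,3,563,809
14,own,non_contrastive,2.70,3,2,583,808
15,pest,contrastive,0.49,4,4,608,943
15,peek,non_contrastive,0.64,4,3,581,836
16,pound,contrastive,1.26,5,4,589,815
16,plate,non_contrastive,1.47,5,4,573,829
17,sand,contrastive,2.05,4,4,620,789
17,sink,non_contrastive,1.45,4,4,634,831
18,spent,contrastive,1.88,5,5,645,707
18,stage,non_contrastive,1.63,5,4,666,687
19,toast,contrastive,1.06,5,4,586,926
19,tanks,non_contrastive,1.05,5,5,554,1014
20,waste,contrastive,1.45,5,4,561,811
20,worse,non_contrastive,1.65,5,3,586,771
21,fast,contrastive,2.39,4,4,549,779
21,flat,non_contrastive,1.97,4,4,570,715
22,found,contrastive,2.81,5,4,622,759
22,floor,non_contrastive,2.38,5,4,603,763
23,post,contrastive,1.52,4,4,582,729
23,pink,non_contrastive,1.54,4,4,585,784
24,dust,contrastive,1.78,4,4,547,887
24,drop,non_contrastive,1.79,4,4,595,884
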