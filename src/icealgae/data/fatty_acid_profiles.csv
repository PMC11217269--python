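fa_name,outer_pct,inner_pct
14:0,7.5,5.5
15:0,0.3,0.4
16:0,20,19
16:1 n-9,2.7,8.5
16:1 n-7,49,22
16:1 n-5,0.6,1.5
17:0 Phytanic,0.1,0.4
17:0,0.1,0.5
16:2 n-7,0.9,1.9
16:3 n-4,0.5,1.9
18:0,1.4,6.2
16:4 n-1,1.4,3.1
18:1 n-9,1,1.5
18:1 n-7,0.3,0.7
18:2 n-6,0.6,0.6
18:3 n-6,1.9,1
18:3 n-3,0.3,0.4
20:0,0.2,0.4
18:4 n-3,1.4,2.1
20:4 n-6,0.8,3.4
20:3 n-3,0.2,0.3
22:0,0.1,0.4
20:4 n-3,0.2,0.3
22:1 n-9,0.4,3.3
20:5 n-3,6.9,10
22:6 n-3,0.9,2.1
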