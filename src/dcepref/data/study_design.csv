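task_id,alt_id,provider,location,support
1,1,community health worker,workplace,travel voucher
1,2,expert client,home,phone call
1,3,,,
2,1,family member,home,SMS
2,2,expert client,workplace,travel voucher
2,3,,,
3,1,family member,home,SMS
3,2,community health worker,workplace,phone call
3,3,,,
4,1,expert client,home,SMS
4,2,family member,home,phone call
4,3,,,
5,1,family member,home,travel voucher
5,2,community health worker,home,SMS
5,3,,,
6,1,community health worker,workplace,SMS
6,2,expert client,home,travel voucher
6,3,,,
7,1,expert client,workplace,SMS
7,2,community health worker,home,phone call
7,3,,,
8,1,expert client,workplace,phone call
8,2,community health worker,home,travel voucher
8,3,,,
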