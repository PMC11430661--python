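child_id,age_months,score,event
child-b-synthetic,3,10,
child-b-synthetic,6,14,
child-b-synthetic,9,17,
child-b-synthetic,12,21,
child-b-synthetic,15,24,
child-b-synthetic,18,24,
child-b-synthetic,21,25,
child-b-synthetic,24,25,
child-b-synthetic,28,26,
child-b-synthetic,32,27,
child-b-synthetic,36,28,
child-b-synthetic,40,29,
child-b-synthetic,41,30,cochlear implant activation
child-b-synthetic,45,37,
child-b-synthetic,50,44,
child-b-synthetic,56,51,cochlear implant activation
child-b-synthetic,60,55,
child-b-synthetic,66,59,
child-b-synthetic,72,62,
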