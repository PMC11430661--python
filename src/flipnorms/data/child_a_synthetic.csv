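child_id,age_months,score,event
child-a-synthetic,3,1,
child-a-synthetic,5,2,
child-a-synthetic,7,4,cochlear implant activation
child-a-synthetic,9,11,
child-a-synthetic,12,20,
child-a-synthetic,15,27,
child-a-synthetic,18,33,
child-a-synthetic,21,38,
child-a-synthetic,24,43,
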