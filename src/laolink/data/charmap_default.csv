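source,target
໐,0
໑,1
໒,2
໓,3
໔,4
໕,5
໖,6
໗,7
໘,8
໙,9
ໜ,ຫນ
ໝ,ຫມ
ໍາ,ຳ
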