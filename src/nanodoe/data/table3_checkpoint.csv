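record,name,value
optimum,lecithin_mg,100
optimum,chitosan_mg,23.5
optimum,ipm_pct,2.6
estimated,PS,168.4
expected,PS,179.1
error_pct,PS,6.4
estimated,ZP,33.1
expected,ZP,30.5
error_pct,ZP,7.9
estimated,EE,82.3
expected,EE,79.2
error_pct,EE,3.8
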