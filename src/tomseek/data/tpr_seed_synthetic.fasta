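>TPRSYN01
AKAWTNRGNAYYKQGDYQKAIEYYQKALELDPNN
>TPRSYN02
PEAWRNLGNFYYKQGDYQKAIEYYVKALWLDPNN
>TPRSYN03
AEAWYNLGNAYMKQGDYQKAIEYYQKLLELDPNN
>TPRSYN04
AERWYALGHAYYKPGDYQMAIEYSQKALELDPNN
>TPRSYN05
AEAWNNLGMAHDKQQDYQKAIEYYQKALELRPNN
>TPRSYN06
AEAWYNLGNAYYKQGEYQKAIEQYQKATELDPNN
>TPRSYN07
AEALYNLGNAYYKQGDKQKAIEYYQKALELDPNN
>TPRSYN08
ALSWYNLGNAYYKQGDYQNAMNAYFKALELDPNN
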