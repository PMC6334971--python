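>HSP20SYN01
RSLWPFDEFNNEPFRSLSRMFDDALGRPRVRSYAPSCDIYEDDKEVVVKAELPGVLKEDV
KVSVEDNVLTISGERKSEEE
>HSP20SYN02
MVLIPFDDFFNEPFRSLDRMGDDALGRPAVRSYEPSVDIYEDDKWVVVKAELPGVKKEDV
KVKVEDNVLTISGERKSEEE
>HSP20SYN03
MSLIPFDDFFNEPFRSLGQMFDDALGRPAVRSYAPSVDIYEDDKEVVVKAELVGVKKEDV
HVSVCDNGLTIEGERKDEEE
>HSP20SYN04
MSLIPFDDFFNEPFRSLDRMFDDALGRNAVRSIAPSVDRYEHDGEVVVKAELSGVKCEDV
GVSVEDNVLTISGERKSEEE
>HSP20SYN05
MSLIVFCDYFNEPTRSLDRMDDDASGRPAVRSYAQSQDIYEDDKEVVVKAELRGVKKEDV
KVSVEFNVLTISGERKSEEY
>HSP20SYN06
MSLIPFDDFFNEPYRSLDRMFDDALGRSAVRSYAPSVDITEDDKEVVVKAFLPGVKGEDV
KVSVEQLVLTNSGERKSEEE
>HSP20SYN07
MSMIPFDDFFTEPKRSDDETFDDALGWPAVRSYAPKVRIYEDDKEVVVKYELPGVKKEDV
KVSVEDVVLTISGERKDHEE
>HSP20SYN08
MSLIPFDDFENEPFRSLDRMFRDALGRPAVRSYAPSVDIYEDDKEVVVKAELPGVKKEDV
KVSVEDNVLTISGERKSTEI
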