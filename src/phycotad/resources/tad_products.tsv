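canonical	pattern
flp1	\bflp[-_ ]?1\b|Flp pilus assembly.*pilin Flp(?!.*2)
flp2	\bflp[-_ ]?2\b
tadV	\btadV\b|\bcpaA\b|prepilin peptidase.*(Flp|Tad|Cpa)
rcpC	\brcpC\b|\bcpaB\b|Flp pilus assembly protein RcpC
rcpA	\brcpA\b|\bcpaC\b|Flp pilus assembly.*secretin
rcpB	\brcpB\b|Flp pilus assembly protein RcpB
tadZ	\btadZ\b|\bcpaE\b|Flp pilus assembly.*ATPase.*CpaE|pilus assembly protein TadZ
tadA	\btadA\b|\bcpaF\b|Flp pilus assembly.*ATPase.*(CpaF|TadA)
tadB	\btadB\b|Flp pilus assembly protein TadB
tadC	\btadC\b|Flp pilus assembly protein TadC
tadD	\btadD\b|Flp pilus assembly protein TadD
tadE	\btadE\b|Flp pilus assembly pseudopilin TadE
tadF	\btadF\b|Flp pilus assembly pseudopilin TadF
tadG	\btadG\b|Flp pilus assembly protein TadG
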