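ENTRY       M00175            Pathway   Module
NAME        Nitrogen fixation, nitrogen => ammonia
DEFINITION  K02588+K02586+K02591-K00531
///
ENTRY       M00531            Pathway   Module
NAME        Assimilatory nitrate reduction, nitrate => ammonia
DEFINITION  (K00367,K10534,K00372-K00360) (K00366,K17877)
///
ENTRY       M00530            Pathway   Module
NAME        Dissimilatory nitrate reduction, nitrate => ammonia
DEFINITION  (K00370+K00371+K00374,K02567+K02568)
            (K00362+K00363,K03385+K15876)
///
ENTRY       M00529            Pathway   Module
NAME        Denitrification, nitrate => nitrogen
DEFINITION  (K00370+K00371+K00374,K02567+K02568) (K00368,K15864)
            (K04561+K02305) K00376
///
ENTRY       M00345            Pathway   Module
NAME        Formaldehyde assimilation, serine pathway
DEFINITION  K00600 K00830 K00018 K11529 K01689 K01595 K00024 K08691
///
ENTRY       M00937            Pathway   Module
NAME        Coenzyme F420 biosynthesis
DEFINITION  K11779 K11780 K11781 K14941
///
ENTRY       M00935            Pathway   Module
NAME        Methanofuran biosynthesis
DEFINITION  K09733 K07144 K18933 K07072
///
ENTRY       M00597            Pathway   Module
NAME        Anoxygenic photosystem II
DEFINITION  K08928+K08929+K13991+K13992
///
ENTRY       M00176            Pathway   Module
NAME        Assimilatory sulfate reduction, sulfate => H2S
DEFINITION  (K13811,K00958+K00860,K00955+K00957) (K00390,K05907)
            (K00380+K00381,K00392)
///
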