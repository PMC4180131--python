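>seedR2_01 synthetic seed repeat
LKKGPTWSVEDAILVDYIKAHGEGKWNAVARSTGGLNRCGKSCRWRANNYLRP
>seedR2_02 synthetic seed repeat
LKKGPTWSVEDAPLVDTIKAHGEGKWCAVARSTGGLNRCGKSCKWRANNYLRP
>seedR2_03 synthetic seed repeat
PKKGATWSVEDAILVDYIKAHNEGKWNAVARSTGGLNRCGKSCRWRANNELRP
>seedR2_04 synthetic seed repeat
LKKGPTWSVEDAILVDYIKAHFDGKWNAVARSTGGLNRCGKSCRWRANNYLWF
>seedR2_05 synthetic seed repeat
LKKGPTWSVEDARLVWYIKAAGEGKWNAVARSTGGLNRCGKHCRWRANNYLRP
>seedR2_06 synthetic seed repeat
LKKGPQWSVEDAILVDYIKAHGEGKWNAVARRTGGLNRCRKSCRWRANNYLRN
>seedR2_07 synthetic seed repeat
CKKGPTWSVEDAKLVDYIKAHGEGKWGAVARSTGGQNRCGKSCRWRANNYLRP
>seedR2_08 synthetic seed repeat
LKKGPDWSVEDAILVDAIKHHGEGKWNAVARSTGGLNRCGKNCRWRANNYLRP
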