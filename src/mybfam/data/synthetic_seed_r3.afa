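>seedR3_01 synthetic seed repeat
NEIKNYWNTHELKKKLIKSGIDGPQWHLIANHLEGRTDNEIKNHWNSTLKR
>seedR3_02 synthetic seed repeat
NEIKNYWNTHELKKKLIKHGCDGNQWHLLANHLEGRTDNEIKNHWNSTLKR
>seedR3_03 synthetic seed repeat
HEIKNFWNTHELKKKLIKSEIDGPQWHLIANHLEGRTDTEIKNHWNSTLKR
>seedR3_04 synthetic seed repeat
NEIKNYWNTHELKKVLIQSGIDGPQWHLIANHLMGRTDNEIKNHWNSTLQR
>seedR3_05 synthetic seed repeat
NEIKNYWNTHELKKKLIRSGIDGFQWHLIANHHEGRTDNEIKNHWQSTLKR
>seedR3_06 synthetic seed repeat
NDIKNCWNTHELKKKLIKSGIDGPQWHEIANHLEGRTDNEIRNHWNSTLKR
>seedR3_07 synthetic seed repeat
NEIKNYWNTHELKPKLIKSGIDGPQWHLIANHLEGRTDFEICNSWNSTLKR
>seedR3_08 synthetic seed repeat
NEIKNYWNTHELKKKLIKSGKDGPQWHLIDNHLEGRTDNEIKFHWNSTGKR
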