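>CDC5_landmark synthetic CDC5-type landmark stand-in
VKAKRTGPVERNLKKGPTWSVMDAILVMYIKAHGEGKWNAVARITGGLIRCGKSCRWRAN
NYLRPNFIKNHWNTHELTKKLIKSGIDGPQWHSIANHLEGRTDNEIKNHWNSTLKRILRH
EPSDNKKGRTKDIYDLFDWGCWANQSKNWSRGPPKRYINNADAELDITNHEKKHIGGGVY
GNHDDRYVHIRLDRGNETESRCEKGFRGRTNDIKPHSVLLVRRQWDLIEIKGGKANVKGN
WAIHWDNVTNRDGGRIKRAPNWKRHLKKGKSWRKMYTWLPRLKGRSKRKNIAEENAWNMN
KNYISSKIEYIRDNYKRVAINWAKLEKKAASYRRKNLFLANKLPLINKFKVDIGGKVIKE
SCGCSHTRNINITLLAHKNKAGTYHVTMWVKKGGEKKKNKPNDIRSTSRTDNCELKQIGH
IWNMHKIGNDRHRPLE
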