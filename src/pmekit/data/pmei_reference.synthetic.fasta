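>PMEI_REF_SYNTHETIC synthetic stand-in for the kiwi PMEI structural reference (mature-protein numbering); curated panel residues placed at their documented positions
SGEFIAFICHKGTYMNLCRVALMRHQCYTHKQLLYLWLWMCQEGAEAQICGPWIFGLLHE
DQHSGWNEGLPITCQENQNDVIDTLCYDVVEVQVWDEMWRKPQCSMFEDGKWTCLDIAAN
ICEKALNQNNAQWRDQLLTWIPSVIRPLQESDCVT
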