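>synthetic_omcs_ref synthetic hexaheme OmcS-like reference (simulated, not a database accession)
EFSLTIRVTFKGTTLGDGEDTMYGKWQIKSKMMMMYGWFDIGQFFWTNWKDVDKMCRECH
GDAFRNKRKYGRGPPWKDLPFYNMPPLNLYWNAKIQNEPAAAGWAPAAIELAVMAARCKM
CHRPRESTNKILTPFGFLIEQRKDLIKFAEVNNFRSWIAYWPYDPQFFNKNFLINQMNGA
RWPGLMCLECHVKATAGKVRQMQVWSNFEKQFQTTKEWFQWYPLFSLILEEKPKAIDDGP
KDPCWWCHWGTEIETDNEWFMYNVYEQTVAWQGIIKYGFPRWTTITRNSYTVVQGWSDAF
CMWCHSFQDALMRDPQNASDVRAMWAPDVFMPIIEWSIEMVVFRDMRDNFFTASISVYKY
SCWYCHWTKYVMDYQFFFLRGYAQQPSVMGLVSDWFITQPDVMKQALPQQLEFQESQYAQ
FPVQTLMNIL
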