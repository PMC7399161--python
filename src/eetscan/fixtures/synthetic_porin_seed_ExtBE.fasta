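>ExtBE_seed_00 synthetic ExtB/E-family porin seed (simulated, not a database accession)
AKLIPLATWLMTYGEMSDPLPEYDRMIMLVYWFAEDVVMKYVSYVYLMGWWWQKNETFKV
GSGSSGSSVDFDLDFELEVNLSGSGSSGGLDVDLEFNVDVKVSSSSGSGGFDVDFNVEFE
FKIGGGGSGGGFEVNLKLKLNFNFSSSSGSGGFKLDVEINLDIEISSGGGSSSIDFKVEF
ELEVNIGSSGSSGGFKFKLEVNVNFELSSGSSGGSFDLEVNLKININFGSGSSSGSLDVD
VNVNIKFNIGSSGSGSSINVKFKFKLNLDFSSSSGGGGFKVEVNFDLDFELGSSSGGSGI
EIDLELKLKIDIGSGSGSSSLEFDIEIKVDLEISGSSGGGSVKVEINLKFDFDFGGGGSG
SSVNLEFNLKLDFNFSGGSSGGSLNVEIKLEFDLKLSSGGGSSGPSFPEVSNVRNAFPAS
LTWW
>ExtBE_seed_01 synthetic ExtB/E-family porin seed (simulated, not a database accession)
AKLIPLASWLMTYGVGTDPLPLYERNIMLVYFFAEDVVMKYVTYRALMGPWKQKNEAFKV
GSGSSGSSVDFDLDFELEVRISGSGSSGGLDIDLPFNVWVKMMSASGSGGFDNDFNVIFE
YKISGKGSGGGFMVNLKLKLNFVFPTYSFSGGFKLDVEINLDIEISAQGGSQSIDFKVEF
ELEVNIGSSGSKGGFKFKLEVNVNFELSSGLSGGSFDLEVYLKININFGSGSSSGSLDVD
VNVNIKFNIGSSGSGSSINVVFKEKLSLDFSSSSFGGGFKVEVNFDLDFELGSWPGIMGI
EIDLELKSKDDIGSGSGSSSLEFDIEIKVMLEISGDSGGMSVWMENMLNFDFDFGGGGSI
SWVALEFNLKFDFNFSGGSSGGSLNVEIKLEFDLKLSSGGGSSGPSFPEVSNVRNAFPPS
LTWW
>ExtBE_seed_02 synthetic ExtB/E-family porin seed (simulated, not a database accession)
AKLYPLATWLMTYEWMSAPLPEYDFMIELVWWFAEDQVMKTYSYVYLMGQDWQKNEEFKV
GSGSSGSSNNFSLDFELEVNLRGSGSSGGIDVDLEFNVDRKVSSRDGSGGFDVDFNVEFE
FKAGRGPSGGGFDVNLKLILNFNFSRSSGKNGFKLDVEMNLDIEIDSGGGSSYIIFKVEF
ELEYNIGDSGSSGGFKFKLPPNYNFELSSGSSGGSFDLEVNLKININFGSGSSRGSLDVV
VNVNIKFNTWSSGSGSSENVTFKIKPNLDFNNSSGGGGFKVEVNFDSNFELYSSSGGSGI
EIDLELKLKISKYEGSGSSSLEFDIERKVFLEISGSSGGGSVKVEINLKNDFDFGGGGSG
SSWNLEFNLPLDFNFSWMSSGGSKDEEIKTEFDLKLSSGGPSSNPSFEEIINVRGAFPAS
LTWW
>ExtBE_seed_03 synthetic ExtB/E-family porin seed (simulated, not a database accession)
FKLIPLATWLMTYGEMSDPLPEKAYMVMLVYWFAERVVMGYVSYVYLMGALWQKNETFKV
GGGSSNSSVKFKLDYELEVNLTGRGSSGGLDVDLEFNVDVKVSSSSGSGGFDVDFNVEFE
GKIGGGQSGVGYEVMLKLKLNFNFSSTLGSGTKKLDVEINLDIEISEGGGSISIDFKVSG
YMEVNIGSSGSAGGFKFLLEVNVNFELSSPDSGGDFDNEVNPKINIARGSGSSSGSLDVP
VNVNIKFNIGSSGDGSSINVEFGIKLWLDFSFSSGGGGFKGEVNMDLDFQRRSSSGGSGL
MIDLEIKLKIDIGSGSGSSSLEFDIEIDVDMEISGSSGDGSVKWEINLKFTFVFGGGAEG
SSVNLEFNKKMDFNFSGGSSWGLQRVVIKSYFDLKLSSGGESLWPSFPEVSNVRNAFPAS
LTWW
>ExtBE_seed_04 synthetic ExtB/E-family porin seed (simulated, not a database accession)
AKYIPLATWLMTWGLMSDPLPEYDRMAMLVYWFAEDVVTKYVSLVKLDLWWWQKNETFKV
GSYSTGSSVDFDLDYELEVNYSGSGSSGGLDVDLEFNVDVKVSSSSGSGAFDVDFNVEFY
VKLGGGGSGGGFEVNLKLKLNPNQSSSSGWGAFKLKVEINLDIEISSGGGGSMIDFKVEF
ELEVNIGSSGSSGGFKLPLEVNVNFEWSSGSSGGQFDLEVNDKININFGPGLSSGSLSVD
VNENIKFNMGSSGSGSSINVKFKFKLNLDFASSSGGGGYKVEVNFDKDFELGSSSGMSGI
EIDLELKNKKDIVSGDGSSSLEFDIEIKLDLEISGSSGGGSVKVEINLKFMFWFGGNGSG
SSVALEFFLKLDLNFSLGSSGGSLNVEIGLEFALKYSSGGGSSGPSFPEVSQVINAFPAS
LTWW
>ExtBE_seed_05 synthetic ExtB/E-family porin seed (simulated, not a database accession)
AKMIGLATWLMNYENMSDPEPERDRMIMLVYWFAEDVVMKYTSYVYLMGWSWQKNETFKL
GSGSSGSIVDFDLDTEFEENLSGSFSGGGLDVDLEFGVDNKVSSSSGSGGFDVDFNVTFS
FKIVGGGSGGGFEVYLKLKLNFNFSSSSKNGDFKLDVEINLDIENSSGGGSSMIDFKVEF
ELEVNNGSSGSKGGFKFKRTVYVNFELNSGTSGYSFDAETNLKININFGSGSSSGSLDVD
MNVNKKFNIGSSGSLSSINVKFKFKLNLDFSSSSGGGGFKVEVNFDLDFELGSSSIWSFI
TIPEELKLAIDIGSGQWSSSLEFDEEIKVDLEIRGSSGYGSVYVEINLKLDFDFGGGGSG
SSVNLEFNLKLDFNFSGISSGGSMNVEVKLEQDLKASSGGGSSFPSFVTISNVRNANPAS
LTWW
>ExtBE_seed_06 synthetic ExtB/E-family porin seed (simulated, not a database accession)
AKLIPLATWPMTNIEMSDPLPEYDYMIMLVYEFAQDVVMKYVSYVYLMGWWWQKNETFKV
GEGSSGSSVDFALDFELDVNLMGSGSSGGLVVDLEVNVDKKVSSSSGSGGFDVDLNVEFE
FKEGGDGSGGGPEVNLFFQLKFNVSSSSGSGGFKLDVEINLDIFISSGGGSSSIDFKVEF
ELEVNMGSSGSFGGFKFKLRVNVNFETSSGSSGGVFDLEVNLKININFGSGSSSGSLDVD
VNVNIKFNIGSSGSGSSINVKFKFKLNLEFSSSSGGGGFKVEVNFDLDFELGSQSGGSGI
EWDLLLKLMIDSGSGSGSMSLNFDIEIQVDLEISVSEGGSSVKVEINLKFDEDFGGGGSE
SSVNLEFNFFLDFNISGGSSGLSLNVEIKEEFDLKLSIGGGSSGPEFPYVSNVRNAFPYS
STWW
>ExtBE_seed_07 synthetic ExtB/E-family porin seed (simulated, not a database accession)
AKLIPLATWLMTYGEMSDLLPEYDRMFMLVYNFAQDVVMKYVKYVYLMGWWNDKNETFKV
ESGSSGSSDDFDLDFELEFNLVTSGSSGGLDVDLKFNFDVKVSSSSGSGGFDVFFNVEFE
FKIGGGGSGGGFIVYLKTKLNFNFSSSSGSLGFKLDVEINLDIEWSSGDGSSSIDFKVEF
ELRVNIGSSGSSGGDKFKLEVNVNFPLSSKSSGGSGRLEVNLKPNINFGQQSSSGSLDVD
VNVNIKFNIGSSGSGSSINVKFKFKLNLDPSSSSGGGGFMVEVNFDLTFELGSSSGGSII
EIDLELKLKIDIGSGSGSESLEFDMEIKVDLERSGSSGGGSVKVEINLKFDFDFGGGGSG
ESVVLEFALKLDFNFSGGSSGGSKNVEIKLEFDFKLSSGGGSSGPSFPEVSNVFPAFPAS
LTPW
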