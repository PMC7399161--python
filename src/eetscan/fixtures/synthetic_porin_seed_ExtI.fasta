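>ExtI_seed_00 synthetic ExtI-family porin seed (simulated, not a database accession)
PFIVTDTYAWGPTYQYWEDQIQPLGQFYWTTRFFQLKFQGMPFTWPDGVPTGWFYVIGMR
GGSGSGGGLNIKFKVDFDFNLGSSGGGGSLEFKVNFDIEIEIGSGGSSGSFELKLEIKID
FNVSGGSGGSSLKIELDFNIKLNISGGGGSGSVDFKVKVKIELKVGSSSGGSGFEFKLEF
DVNIEFSGSSSGGGLKIELNIDIEIEVSSGGGSSSFKFDIKINLEFNFSSSGSSSGFEVD
LEIEVEVKVSGSGGGGGVNLNVNIDFEINLGSGGGSSGLNINIDLNIDVEIGGSSSGGGI
KFEFNVELDVKLSSGGGSGSLDLKVDVDINLDVGSGSSGGSVELDLNVEFKFDLSGSGSS
GSVKVELEVNLDFKVGGSSSGSGIKLNLNLDVEVEFSGSGGSGSGSTYADTPTQMMQLTN
FIND
>ExtI_seed_01 synthetic ExtI-family porin seed (simulated, not a database accession)
PFIVTDTYAWGNTYSYWEKQYQPLGYFYWTTRWFQLKFQGMPFTSPDGVPTSWYYVIGMR
GGSYSGGRLQIKFKVSFDFNLGSSGGGGALEFKVNFDIVIEIGQGGNSGSLELKLEIKID
FNVSGGSGGSSLYIEFDFNIKLNINGGGGSGSPDFKVLVKIENMVGSSSGVSGFLFPLMF
DMNIEFSISSSGGGLKIELTIDIQIEVSSGDGSGSFKRDIKISLEFNFSSDGSSRGFEVD
LEIEVNSKVSGSGGGGGVNLNGNIEFEINLGSKGGSSGGNGNAGLNIDVEIGGSSSGGGK
KFVFNEELDVKLSSGGGNGSLDLKVDVDINLYVGSGSSGGSVELDLNVEEKFDLSGSGPS
GSVKGINEVNLDFKVGGSSSGSGIKLNLTLDVRVEFRGSPGSGSASTYLDTPTQMMQLWN
FIED
>ExtI_seed_02 synthetic ExtI-family porin seed (simulated, not a database accession)
PRIVTDTYARGPTRIYWEDQIQPLGAFMWTTMFFQLKFQGMPFTAPDYVPTGWFYKIGMW
GGSGSGGTLNWKFVVRFSFNLGSPGGGGSLEFKVSFDIKREIGSGGSSGSAELKLEIKID
FNVRGGNGGSALKIELDFNYKLNISYGGGSGSVDFKKKVKIELKVGSSPGGSGWEFKQEF
DRNIEFSGSSSTGGMKIELNWDENIEVSDGGGSSSEKFDIKINLEFNFSSFESSSGFEVD
LIVEVEVKVSGSGGGGGLNLTVNIGFLINLGSGGGVSGLNINIDLNIDVMIGGSSSGGGI
KFESNVETNVKLVSGGGSGPLSLWVDVDINLDVGSGSSGGSVELDLEEEFNFDLSMSGSS
GSVKVEGEVNPDFKVWGSSSGWGIKLNLNLDVEVSFWGSGGSGSGSTRFDTPTAMMQLTN
FIVD
>ExtI_seed_03 synthetic ExtI-family porin seed (simulated, not a database accession)
YFIVTVTYAWGWTYQYWEDWIQPLGQFYWTTLFFQLKFQGMAVTWPIRVPTGQFYEIGMR
GGSGMGDGLNIKFKVDPDFDLQSSFGGGSLEFKVNFDIEIEIQSGGSSGSFELKEEIKID
VNVYGGSGGSSLKIDKDFNIKLNESGGGGLGSVDFKDKVKWELKVGSSSGGSGFEFKLEF
AVNDFFSGSSSGGGLKIELNTDIEIEVPSQGISSSFKIDIKDKLVFNFKSSGSSSGFEVD
SEIDVEVMVSGFGGGIAVNLNVNRDFNIWLSSGGGSSGLNRNIDLNIDVEIGGSSSGGGP
KFEFVVELDVKLPSSDGSGSLDLKVDVDTNLRLGSGSSGGSVELDLNVEFKFDLSGSGSS
PFVKVELEVNLDFKVGGSNAGSGIKLNLNDDGEGEFSGSGGSMNGSTYADAPTQMMQLTN
FIPI
>ExtI_seed_04 synthetic ExtI-family porin seed (simulated, not a database accession)
PFIVTDTYAWGPEYQSWEDQIDPLGQFYWTTRFFQLKFQGMPFTWPDGVPTGWFYKIGAR
GGQGSGGLWNIKFKVDFDFILGSSNGGGSLEFKVNFDIEIEIGSGGSSGSFELKLQIKID
ENVSGGAGGSSLKIEQDANIKLKISGGFGSGSVGFKVKVKIELKDGSSSYGKGFEFKLEF
DVNIEFSGSTSGGGLKIELNIDIEIEVSSGGGASSFKFDIKANLLINFSSSDSSSGFEVD
LEISPEVKVKGDGGGGGVNTNQNIDFEINLGSGKNSSLLNIIIDENIDVEIGYSSSGGGW
KAEFNVTPDVKLFSGGASGSNQLKVDDDINLDVGSQSSGNSVELDLNVEFKTQNSGSGSS
GSVKPEWEVNLDFKVGWSSSFSFIRLALNLDQEVEFSMEGGSGSGSTYADTPTQMMELDN
FIND
>ExtI_seed_05 synthetic ExtI-family porin seed (simulated, not a database accession)
PFIVTDTYAWGPTYQYWEDQIQPLGQFYWTTRFFQLKYQGSPFTWPDGVPTGPFYVIGYR
GGSGSGGGLSIKFKVDLNIALGSSGGGGSLEDKVNFDIEIEIASGGSSGSFELKLEIKID
QNVSGGSVISELKIELRFNIKLNISGGGWSGSVDFKVKYKIENKVGSSSGQSGFEFQLEV
DMQYEKSGSSSSGRLKIVLYIMIEIEVWSGGGSSNKKFDIKINLEFNQSSSGSSSGFEVA
LEREVEVKVSGSGNWGGVNLNVNIDFQINLGSGGGSSDLNSNWDLNIDVEIGGSSSGPMI
KIEFILFLDWKLMSGNGSKSLELKVLVDINLDVGSGSSGGPVELFLNVEFKFDVSGSGSS
GSVNVELEVNLDFKLGGSSSGSGIKLNLNLWVERPFSGSGLSPSGSTYADTPTQMMQVTN
FIND
>ExtI_seed_06 synthetic ExtI-family porin seed (simulated, not a database accession)
LFIVTDTAAWGPEYAYWEDQWQPLGQFYATTRFFQTKFQGMPFTIPDGVPTGWFYVIGMR
GISGFGGGTNIKFKVDFDFNLGSSGGGYSLEFKVNFDIEIEIWAGASSGSFELKGEIKID
FDVQWGSGGSSRKIELDFNIKLNSTGRGGSGSVDFKVKVKIELKVTSSSGGSGLEFKLEF
DVNIEFIGSSSGGGLKTELNIDIEIEVSSGGGSKSFKFDLEPNLVGNFSSSGSSSGFEFD
LENDVEVKVRGSGGGGGVNLNVNIDFEINLGSGGGSAALNINIDLQIYVEIGGSSSGGGS
KPMFNVEVKVKLSSGMGSGSLDLKVDVDIFLDVGSRSSGGSVELDLNPEFKFQESGSGSS
GSVKVELNVFSDFKVMGPSEGTFIKLNLNLDVEVEFSGSGGSVSGSTYNDTPEQMMQLTN
FIND
>ExtI_seed_07 synthetic ExtI-family porin seed (simulated, not a database accession)
PFIVTNTYAWGPTYQYWEDIIQILGQFYWTTRPFQLKFQGMRFTWPDGVPTGWFYVIGMR
GGGGVMGGLNLKFKVDVDFNLGSSAGGGSLEFKVNFDIEGEIFSGGSSGSFELKLEIKID
FNVSGGSGISSLKILLDFNIKSNISGGGGSRSVDFNVKVKIELKFGDSSTDSGFEFKLEF
DVNIEFSGSSIGGGLKIELNIDIEIEVSSGGGSSSFKFSIKIILPFNFSSSVSSVGFEVD
LEISVEPKVSGSKGGGGVNLNVNIKFEINLGQGGGSSGWFINIDLNIDVEIGGSSSGGPI
KFEFNVEFDRKLSSGGGSGSIDLKVDVDINLDVWSGNSGGSVELDLNVEFKFDLSGSVSS
GSVKVELEVNLDMKVGGSSSGSGIKLNLNLDVEVEFSVSGGEGRGSTYADTETQMMQQTN
FIND
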