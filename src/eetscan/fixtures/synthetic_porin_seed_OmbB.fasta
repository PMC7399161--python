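>OmbB_seed_00 synthetic OmbB-family porin seed (simulated, not a database accession)
QSDQQYDMSNAYQNPTDGQGNAPTREFWGEAPNTMPNRNVLTIAIWRPMSTSYKQDWQPE
SGGGGGGGVKVDFDIDIEFDLGSGGGGSSIEVDFDIDFEIDLSSGGSSSGVDLDLDVEFN
INLSSGGSGGGFDVNVDVNLKLKLSGGSSGSSLDLNVKLDIKVKVGSSSSGSGIEVEIKV
EINIEFSGSGGSSGIKIKIKFDINFNLGGGGGSSSIKIKVKFDFDIKFGGGSGSSGLKVD
LDVDLELEFSGGSSGGGLNINVNFNVNLKLGSSSGSGGFEFKIKIEINLDVGGSGGSGSV
KINVDLEININFGSSGGGGSFKLKLNVDIEFEVSSSGGSGGIDVDFKINFNLNVSGSSSS
SSFKVDVDLNIEVKFSSSSSGSGINIEINFEVEFDVGSGGGGGSVWGIRMYGQVWWLKNW
MYYW
>OmbB_seed_01 synthetic OmbB-family porin seed (simulated, not a database accession)
QMDFQYRMENAYQNPTRGQGFAPTDEFWGLARNTMPNRNVLTIAIWDPLSTSYKEEWQPE
SGGGGGGGVGVDFDIDIEFDLGSVGGSSSREVKFDIDPFIDLSPGGSDSGVDLDLDVEFN
INLSSGGSGGGWDVNVDVSAKEKLSGGSSGSNLDLNVKLTISVKPGSSSSGSGIEKEQKV
EINIEISVSGGFSKIVIKLKFDINFNLGGGGGSSSIKIKQKFDSDIKFGGGSGSQILKVD
LDVDLELEFSGGSSQGGLVINVNYNVNLKLGTSSGSGGGTFKQKIEINLDVGESGGSGSV
KFNVILEINRNFGSSGVGPSFKLKLNVDIEFEVSSSGGSGGIDVDFYINFNLNVSGSSRS
RFAKVDVDLNIEVKFSSSSSGSGINIANNFEVEFDVGQGGGGGSVKGIRMWGQVWWNKQR
MYYW
>OmbB_seed_02 synthetic OmbB-family porin seed (simulated, not a database accession)
QSDQQYDMSNAYQNPTDGQGNAYTREFWGRAPNTMPNRNKLAPAIMRPMSTSYKQDWQPE
SGGGGGGGVKMDFFIDIEFDLGSGGGGSSIEVDFDIDFEGDLSSGGSSSGVDLDLMVESN
INLSSRGSGGGFDVYVDVNLKLKLSGGTSGSLLDLNVKLDIKVKVGFSSSGSGIEVEIKV
EIFIEISGSGGSSVIKLKADFDINFNLGWGGGSLSIKIKVKFDFDQKFGGGSGSYGLKVD
LFVDLELIFSQGSSGGGLNINVNFMVLLKLGSSQGSLGFEFKIKIEINLDVGGSWGSGSV
QINIDLEANINFGSSFGGGSFKLKKVVDIEFESPSSGGSGGIDVDFKINFNLNVSGSSSS
SYFKVDYDLNIEVKWSMSSSGSGWNQENLFEVEFDVGSGGGVGSVRQIDEYGQVMWLKNM
MYYW
>OmbB_seed_03 synthetic OmbB-family porin seed (simulated, not a database accession)
QSDQQTDMSNAYQNPTDGMGNAPTREYWGEAPNDMPNRNVLTIAIGPPMSTSYKQDWWEE
SGPGGGGGVQVDFDIDIEFILGSGGGGSSILVDFDYAFEKDLSSGGSSSEVDLDLDVEFN
INLSSGGTGGWFDVNVDVNLKLVLSGWSSGSSLDLNAKLDIKVKVGSSSSGSGIEVEIKV
EINIEFLGSGGSSGIKIKIDFDINFNLGGGGGSSSQRIKVKFDQTIKFIGGSGWSVLLNQ
LDVDLEPEFSGGSSGYGANMNVNFNVNLKLGSSSGSTGYEFKIKIEINLDVGGIGGNGSV
KINDDMEININFGSSGGGGSFELKVFVQIEFEVFASGLSGGIDVDDKINFELNVAGSSSS
SSFFVDVDLNIEFKNSSSSSWSGINIEINFEVEFDVGSGGGYGSVWGISMQGQVVWLANY
MYYL
>OmbB_seed_04 synthetic OmbB-family porin seed (simulated, not a database accession)
QSMYQYDMPNAYYNPTDGQGNLPTREFWWEVQNEMQNRNVLSYAIWFPMSTSYNQDWQPE
SGGGGGGGVKVNFDIDIEFDLKSGGGGSSIEVDFDIDFWPDLSSGKSSSGVALDLDVEFN
INMSSGGSGGGFDVNVDVNLKLKLSGGSSGSSLDLNVVLDIKVTVGSWSSGFGIEVEIKK
EKMIEFSGSNGSSNIKIKIKFDINFNLGGGGGSSYWKIKKYFDFKIKFGGGSKSSGLDVD
LDVSLELEFSSESVIWGQNANVNFNVNLKLDSDNGSGGFEFKNKIEGNSDVGGSGGSGSV
TINVDLEININFGSSGGQGSFKLTLNVDIEGEVSPSGGSNGIDVPFKIVFNLNKSGWSSS
SSFWVDVLLNIEVKFSSSSSGAGIMITINFEVEFDVQSGGYGGSVWGNRMYGQVWWLKMF
MYPW
>OmbB_seed_05 synthetic OmbB-family porin seed (simulated, not a database accession)
QGDQQYDMSNAAYNKTDGQGNAPTREFWGEAPNTMPNRNVFTIGIERPMSTSYKQKWQPM
SPGGGGGGQKVDFDIDIEFDMGSGPGGSWIEVDFDIMFEQDLSMGGSSSGVDLDSDVEFN
INASSGGSWGGFTVNVDVNLKLKLSGGLSGSSLDLNVKKDIKVKVGSSSSGSGIEVEIKV
EISGEFSGSVGSSGIKGKIKFDINFNLGGGGGSSSRVIKDKFDFDAKFGGGPGSSGLKVD
LDVDLELEFSGGSSGGGQNINEWFNVNTKLGSSSGSGAFEFKIQTEENLDVGLSKGEGSV
KIMVDLEVNINFGSSQGGSSFKGKLNVDIEDERSSSGGEGGIDVDFKILFALYVYRSTSD
SSFKTDRDDNIEVKFSSSSSGLGINIEINYEVEFDVGSGGYIGSVQGTRMYGQVWWLKQW
TYYS
>OmbB_seed_06 synthetic OmbB-family porin seed (simulated, not a database accession)
DSDQQAMMSNAYQKPTDGQMNAPTRMFWGEASNMMPNRFMLTIAIWVPMSTSYKQDWRPE
SGGGGGLGVKVDFDIDIELLLQSGGGGSSIEVDFDIRFEIDLSSGGSSSNVDLDLDVEFN
KNLSSGGSGGGVPVNVWVNLKRKLSGGSSGSSLDLFFKLDIKVKIGSSSSGPGIEVEIKV
ENNIEFSTSGGSSGIKIKIKLDINFNLGGGYGSESIKNRVKFDFDLKFGNGSTSSGLKYD
LDVDLELEFSALSSGGGSNINVNYNVNLKLGSSSGSGGFEWKFKISINLDVGGSGGSGSV
KIMVDLEININWGSSGIGGSFKLQLNVDIRFEVSFSIFSGGIDVDFKINFNWNVSGSSAS
SSFKVDVDLNIEVDFSSSSSGQGINIEINFEVEFDVGSGGGGGSVGGIRMYGQVWWLKNW
MYYW
>OmbB_seed_07 synthetic OmbB-family porin seed (simulated, not a database accession)
QSPQQYDYSNAYQNPTDGWGNAYTREFKYEAPGTTPQRNGLTEAIWRPSSQSYKQDWQPE
QGGGGGGGVKVDFDPDIEFWLGSGGGGSIISPDFDIDFENDSSSRGYSSGVDSKLDGEFN
INLSSGGSEGGFDVNGDVLLKLKRSGGSSGSSLDLNVKLDIKVKVGTASSKSGIEAEIKV
EINIEFSGSGGSSGIYIKIKFDINFNLGGGPGSSSIKTKVKFDFDIKFGGGSGSSGLKVD
LDVDLELEFSGESSGGGLNINVYFNVNKKLGSSSGSGGFEFTILIYIQLFEGRSGGSGSV
KINVALEIFINFGSSGEGGSFKLFLNVYIEFEVISSGGSGGIDVDFIVNFNLNVSFSLSS
SSFKVDVDWNIEVKFSSSMSGSGINGEWNFEVEFRVGSGGGGGSVGVIRMIGQRWWLKNW
MYYW
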