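>MtrB_seed_00 synthetic MtrB-family porin seed (simulated, not a database accession)
ESDGRVTIALWSKITQVFVYFVQIEVIARTLNRYYTKVASDWWYKIFQGRVWLFYNDLMT
GGGGSSSSVEFEFNFKLNFELSSGSGGGSFDIDLEIEIKIELGGGSSGGSIDIKLEVELE
IEFGGGGSGGGIEVNVEVELNFEVGSSSSGGSVKINLEVKFEIEVGGSSGSGSFNVELDI
EFKLDISGSGSSSSFKIKIEIKVNLNLSGGGGGGSLDVKIKFNINLDLSSGSSSGSVNFN
VNFEINFKFSSGSGGSGLKFKLEIDIDFNFGGSSSSGGVEVDVDVELDIDLGSSGGSSGI
KVKIELEFEFDIGSSGSSSGVDVKVEFEFKVKIGGGGSSGSVEIDFKINLNLDISSSSGG
SSVKVDFKIKFNLKFGSGSGGSGIKLKLKVDFNIKIGSGGSSSGQKPQWTAPFYAGAPQQ
VNFR
>MtrB_seed_01 synthetic MtrB-family porin seed (simulated, not a database accession)
ESDGRVTIALWSKITQVFVYFVQIVVIARGLNVYYTDVAFKWWYKIFQGRVWLFYNDLMT
GGGGSSSSVSDEFNFKLNFELSSGSGGGIFDIDLEVEIKIELGGGSSGGNIDIKPEVELE
ILFGGGMDPGGIEVNVEVETNFEVGSSSTGGSVKIKLEVKFEIEVGGSQGSGSFNVELDI
DFKLDISGSFSSSSFKIKIEIKNNLNLYWGGGPGSLDVKIKFNINLYLSSGLGLGSVNFN
MNFEINTKFVVGSGGKGQKFKLYIDIDFNTGGLSSSGGVAVDVDGRMWGDLGSSGGSSFI
KVKIELEFEPYIGSSISSSGVDVKEEFERKVKIGEGGSSGSVEIDFKINLNLDVSKSFGG
SSVKVDFKIKENLKFGSGSGGSGIKLKLKYDLNLKIGNGSSPSGQKPQWTAPFYMAAPQQ
VNFR
>MtrB_seed_02 synthetic MtrB-family porin seed (simulated, not a database accession)
EPDGRVTIALWSKITWVFVFFVQIEVIARTLNRYYTNVASQWWYKIFQGRVVLFYNDLMT
LGEGSSSSVEFEFVFKLNFEGSSGSGGGSFDGTLEIEMKGELGGGSSGGSIDIKSELELL
IEFGGGGSGGGIEVNVEVELMFEVGSGSPMGPVKMNLEVKFEIEVTGSSGSGSFNVERDD
WFKTDISGSGSTSSFKKKIEIKVNNNLSGGGGGGDLDVKIQFNINLDFSSGSSKDSVNFN
VNFEINFGFSSLSGGSGLKFKLEIDIDFNFGGSSSSGGGEVDVDVELNTDLSSFGDSLRI
KVRIEKEFIFDIFASGSQSGVDVKVEFEFKPKIYGGGSSGSVEIDFKINLNLDISSSSGG
ESVKVDFKIIPNLKFGSGSGGSGIKLKLKVDFNIKIKSGGVSSGQKPEPTAIFYKGAPQQ
VNFR
>MtrB_seed_03 synthetic MtrB-family porin seed (simulated, not a database accession)
ESDGRVTIAAWSKITQVDVYFVQIEVIARTLTRYYTKVASDWWYKIFQFRVWLFYNDLNL
GGDGSSSSVNFDFNFKLNFWLSSGSGGGSFAIDLEIWIKIELKGVSSQGSIDIKLEVELR
IEFTGGGSGGGIVVNVEVPLNFEVGSSLSGTSVKINLEVKFEIEYGGSSGSGMLNMELAI
EFKLDISGSGSSSSFKIKIEIKVNLNLRGGGGGGSLDVIISFNINLWLSSGSVSGMVNFN
VNFEINFKFTSGSGTSGGKFKLEIFIDFNYGMSSSSGYVEFDVDVELDIFLGSSGGSWII
YVKIELNFEFDIGSSGSSEGVDVKQEFEFKVKIGRKGGSGSVFIDFKINLNLDISLSSGG
SSVKVDFKIKFNIKFGSGSGSSGIKLKKSVDFNIGIGSGGSSSGQKPQYTAEFYAGAPNQ
VNFR
>MtrB_seed_04 synthetic MtrB-family porin seed (simulated, not a database accession)
EVVGMVTIPDWSKFTQVFVYFVQIEVFARGLNRKYTMVASDWWYKIFQGRVWLFYKDLMA
GGGGSSSSVSFEFNFMANTYLSSGSGGGSFDIDLETEIKIELGGGSSGGSIDIKLEYILE
IENGGIGMGGWIEGNVEVELNFEAGSSSSAGSVKINLEVKFGITVGGSSGSGSFNVPLDI
EFTLDISGSYSSSSFKIDIEIKVNLNGRGGGGGGSLDVKIKFNINGDLSSNESSGSVIKN
VNFEWGFKFSSISGGSGLKFKLEGWIYFNGGGSSSSPGVEVDVDVELDIDLTPSGGSSPI
KLKIELEFERDIGSSGSSSGVDVRVEFEFKVAIGGGGSSDSVEIDFWINLNLDISYSSGG
TSVANEPKIKLLLKFGSGWGGSGIKLKLKVDFNIKIGSGFNSRGQKPQWTAPFYAGAPQQ
VNFR
>MtrB_seed_05 synthetic MtrB-family porin seed (simulated, not a database accession)
ESDGRVTILLWSMITMVNVYFVQIEVIARRLNRYYTKVASDWWYKIFQIRYWLFYNDLMT
GGMGLFFSVELEFMNKLNFLLSSVSGGGVFKIDLEIEIKIELGGGSSGGSIDIKLEVELE
IESIGGGSGGGWEVNVEVELNFENGSSSSGGSEKINLEVKFEIEVGGSSGSGSVNVPLDI
ELKGDISGSGSQSMFKIKIEIKVNLNLSYGGGGGSLDTKMLFNINDDLSSGSSSGSVNFF
VNFEINFKFSSISGGSPLKFQLEIDIMFNFGTSSSSGGVSGDVDVELDIDWGSEVGSSGI
PVKITMEFEFDIGSSGSSSGVDVKVEDNQKVKIWGGGSFGSDEIDFKDNLNWDISSSSGG
SSVKVLFKWKFGLKFGSGSEGSGIYQKRKVDVNQKIGSGGNSSIQKPAWTAPFYAGAPQQ
VNFP
>MtrB_seed_06 synthetic MtrB-family porin seed (simulated, not a database accession)
ENDPRVTIALWSKYTQVMVYFVQIEVIARTLNRYFTKVASDWWYKIFQWRNWLFYNDLMT
TGGASSGSVEFEFEFKLNFEKFSGSGGGSFDIETEIEIKIENGGGSSGKSIDIKLYVELE
IQFGFGWSGGGIEVNVEVELEPEVGSSSSGGSVLINLAVKFEIAVGGSSGVGSFNVELDI
SFKLDYSGGGSSSSFKIKIEIKVNTSLSGGGGGMSLDVKILFNINLDLSSGSSSGSVSFN
VNMEINFKFMSGSGGSLLKFILDFDIDFNFGGSSSQGGVEVDVDVELIIDLGSSGGSSGY
KVKIEDEFEFDIGSSGSSSGVDVIVEFYFKVKIGGGGSSGSKEYDFKINLNLDISSSSVG
SSDKVDFKIKFNLKFGSGSGGSRIKLKLKVDFNIKIGSGGSSIGQKPQWTAIFYAGEPQQ
VNFR
>MtrB_seed_07 synthetic MtrB-family porin seed (simulated, not a database accession)
ESSRRVTYAMFSVITQVFVGFIPIEVIARTLAMYYTDVASDVWYKIFQGIVWLFYNDNDT
GGGGSSSPVKVEFNFKLNFELSSGSAGGSFDIDLEIEIKIELGEGSSGTFIDGKLEVELE
IEFGGGESGGGIEVNVEVELNFEVGSSSVGMSVKINLEVKFPIEVGGSGGSRSSNVILRI
QFKLDISISISSSSYKIKGELKVELNLLGRGGGGQLDVKIKANIWLWLSSESSSGSVNFN
VNFEINFKFSSGSGGSGLKFLLEIDIDFNFGGGSSSGGVEVDVDVELLIDLGSSGGSSGK
KVKDSLEFETDWGASGSSSGVDVKVEFEFKVKIIGGASSDSVESDFKINTNLDISSSSGG
SIVKVEFKPKFNLKFGSGSGGSGIKVKIKVDFNEKIGSGVSSSGQKPKWTAPFYAGAPQQ
VNFR
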