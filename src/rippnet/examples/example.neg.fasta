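>neg_0
GYCEDTAHSQRSDAVRTRRIKHMVNITKDQLEKMKENVITTYRKPWPVMDYKRKRHYQFQCN
>neg_1
DCVMAYYTDQVDLDTLQEFSQEIMYVLTIWFNTSMSWILCGCSKDRKERMNRPVIRKTFLTEQRRWNGCMIEFGFDP
>neg_2
SKCMAEAFFHKDFYERGIELTTCLMTT
>neg_3
HGCSESYMLKLLQLSGEITHRNPTNCWHYLNIAIQVFPPWTAYEFVQEKVCSMCHSWIKKVIGAYFMYDWLGYVNVNKPQMLDWFFRLGLMEILMPKAICMRHTWHPDAGKHEWDDLGA
>neg_4
ATPCSQVGAKTKAINEGDKAAMMCKETEFNDRSMCKFCDKSEDDENCRHNQEFGQNRNQWIDMLTQLGVDELKSKNREWVV
>neg_5
EWMQKENWWYCETELGWYFECK
>neg_6
LLGTWKKMIMRKWTIWEAWHKKFTEPESNKSSRVHNCTGIRC
>neg_7
LMSCTHYCAQSELMKAQAELVMNSTKINVDMRAWMDQAYKTNSGNYFTHAYMESWPNWCWKAVDTESNKICHNFYLECA
>neg_8
NGLLGMHWLQNDKAKNNWEEWPEDVACYVEQEYFRLGGWFNQRLKLLVSELWWPFDCKATMAFRYSWPWKSYNAKSKHCQGLTMLTFRGKEWRQCSN
>neg_9
GSHTGRSKSIDWQWYRLEKNCPPCTIPPPIHSF
>neg_10
MHIESSPFLVTIQERCDKPFGECYFPNVSECETQTPQGSHNGCRHMPMLLDYIWPGCFSRHKYSYWVCFSWVQPCTIPKEKLWAYVGTCYE
>neg_11
RSDTFAACGPEGHNRRICSHTDCSIMHCKTSLTPLIANTSYVCY
>neg_12
VGNFPNPCWCLCPGDWCGEWPMDE
>neg_13
TWENENRGTKVFAAEWRVDDACPKRLERQKEECCKLVWLRKAGLLKVHQIVDMPMPKQQNRLAKSVSIFNPETQEKLVCACQALFNMGFH
>neg_14
TDKGVTWKPFLKSWLCDCGPAAADPETNKSKEHDAVNMQERWWRAYFLQHDMHWGCVMHHYHVRDLKYVWCYVMYEHVTPLQEHVKWHHNQYVFKEETCAIYILFGGRVFYCHSWKDCV
>neg_15
ITDNCQTLPSDWLICVDMCTWEVELHVDKVTFMNTHFFYQNYSVYKNLVCLSCMTEY
>neg_16
LCTWEHQNLLDGMSWQGLAGESEDGHHCPMAVFHHVKEQAVFCRAADVNSPQLPAGEADDGGQVPRWGQRFVVYMCRMIH
>neg_17
CGCCAGHEESNITKVNHELMNTFHPKKKYTQDYSGFKWMLSRHEGALRRTYRGPVGIKMYELNPIKFWTVEYTTWMNCHWHVKPAKDLQAD
>neg_18
VSACISNDMPSRIAWWCDTEHTDWKHWTLCKPTLKGYMMEP
>neg_19
KEWSCFPGHCHYWVVGAKEKTAHMRVFWLCIEMRGWSHTLHASILYLADVGMVAQYPMGKATTMYLL
>neg_20
HDAVQQGCTTECFVMCHAWCNDSLNQLDIWQCAKYFNEGIGNSMQFY
>neg_21
DVFFELCNLVQTDYIHPTNKDATYWWTSHAKNNWGRVWSCKGFDTAKHCQLRFDWQLAHNTMADQDPYALPELILIIAHASEWCSHLPTWGWALNATYNADMCCPKESLMSKYDIQGYRL
>neg_22
RHYFPIIYFSQYTSIITCPKTEGEPHTNCKFANESCN
>neg_23
ISHYFVWRFMMNPWQREHNEKCGKDTPFHSPTHLIPVVCTAHMYILRSKSSMLTLAFGWEMHGLKVNCLGAECFELCCCCTVCDKGTR
>neg_24
ACLASGNIAMCYHWQFPLEEYECIKPDTFLMQKVWLPWPEDDHFGYCEPWRQDIKSEWHMYGTWIINVRYPDWDQKYMTEAFEVDCVIREWSKLTNIYMPENYSHWLAN
>neg_25
GPTPANHVNVFEISRRHCWHLPINMMLLFTHIKELKH
>neg_26
IYEYMSVDWPWWEVDIKFLQNHVMNVPDVDATFGKMSSAKKCHGLF
>neg_27
HVNDMWATNLTWYLIYGGHVFELWMIKTYLCKQQ
>neg_28
SWGQCAEPEEKSAFLKWIMYVLHYWTNHVAECVILGKNIRAMWNTYWGVNA
>neg_29
WLAAWQWCIRYFDGTLRPTYPCYLIAPVTETMERYTNHIYWSCPNETPLPGKDFALETNGIKHELKAIIKWYWHTPQSCQITGWADRGILSKFNIPWIFMAW
>neg_30
ESDEARMDWLKLTRFRAPHFWLEHTHSAKELMQGEDAIMTLQCMPRIRNCMEHTGGESWGRQQEPKISVQVKADPYDHKLKPFVSKWLFYKIECKCDHAGHAAKQNLLKWYRSP
>neg_31
ICSTCMAKSNWNLVYTIGGYIPGQNVKWQRGRKPVQDDGFQAPECYWQLQAESIRSIWKDLQKFSPDEPPQYEIYNMNVVICRWQAPWTAPFFEPCEILEIWAGGNEVHL
>neg_32
PWSFAPTNLKGVQDESKSSAAFSKINMKGRIALEWWKWKDHHMPDGNADRKGAAHSYAHHNYLHVKHCFCCTGVCDFWAPNSNHWLQVWPLWSTPNCDGIAFLIYFRCKNQNRYSGEI
>neg_33
NLVSKNGFYPEDIMTNHVRLLDGVYKTCLRMFSTMPLVLCCSWLPVNAENCQMKTYLFICDAVNGGLNHNDKFSVCHMMKTGEEYMTYVFWIKTRACTCITREMAIQWCADCKYQY
>neg_34
DSSESFNRKHKGYVDTSLGNVWEC
>neg_35
SGYILKFHYLRDSFSYDHQSIYCVIAPFVKLIKHNLEYSADVMAYCNDCHVWHCMEVEVNAATTNLSMIKMLTFEIKYMSCQWLPSKVS
>neg_36
DMWYPMQWWWMLAQCAPRYWLHGW
>neg_37
TWKPVGVYGAPCDYSMAECALQKAHLQHESYTPIKSSWQMGLDLFCNCFALCCDWMEPYMSEAIMSWKTLTPPPIHCD
>neg_38
LDCKMKKCIWCLQSQYEIIDCGFIWRMYVYKEEGVGEYCPDDIEGKYLGLSHTGFIYWSHCWVEFLI
>neg_39
LSGASLANHYDNKWLLVMQNRMMHNCSLPCPSMSQPDWCVYCFMLNAHFQKGDWDALKEVMNTTTNG
>neg_40
LHVICNCRKISLQTGSAQNN
>neg_41
RDQFSEALSAEWMHVGCPCGVKHVVNSNSSCHKHNFLKWPEHEHCYSVNKKRLMVNIIHAVCPCNMWHGDYLICCCLMKCNYGWISCSGAYCLYGACKNIDLKINIRATQKVY
>neg_42
QNYVGSYLSTGCYFCYMTEVMLLPVHGVHSRGRMLGLISAWLV
>neg_43
KNLSNPMIDRSIASQTWSENMIKIFRNNRQCFYRCEFHPMTSIFDGCFRNILYGMDFSGQNQYE
>neg_44
WSSHYCGLKNNTKVMPNTHTKWNGYLMKFYGWN
>neg_45
QTEGFRIGEDNGDGTKMTCMYCTLWNYNDCRWDHGWEIQKQVCNGNVWGNCCMEHSHEN
>neg_46
MLWIQCGTPQDCPIGKYDMLGNKCF
>neg_47
SDANSKWDKMDRMPIGGADQEASKTHYSRSGWKKFIAKTHKWPHEVALCSARLCNKEASNDVQQIDHVMQYVMSCQNCVGTYYDCASNPWFNHNCVSIG
>neg_48
LWDPIDVKACNSMWKSLPFEPQKTGHWVTSTLFVEHEGDAWNNLVKNKRFPLYQFSISGIAPWNMSSVPPYGYGVWPTPHRLHCRFPQETENREEAHDPEAFMFISPKTWAWKSWY
>neg_49
DMYNEWVNHDDKNNNWVYDHMVWMCGNFFWGNNVLLVKHCNYKVEYEVASRAKLKWMRTVVSSMHASVWHLNDCVNRCPKFVRRTQDQMGLVDMHPENRDEYEKCPWWREELNN
>neg_50
CQNQGVKMMQKASKEAMCVGQQTIVTEKDHLVPEHCHGEN
>neg_51
RYFTIMDAELAEDFMKHEALSFEKPWMSDQEWDVSNHFHLCDEQFWMGGINSHRKIMEEILVHKELLICSFKTMHFAHLWMFNSAEMHWC
>neg_52
TFGFETHVYVAYTTSYGCYWVMLCDLVNWEWSAPLHVEDGCGVIEHSQASSKAYIADWGWKQG
>neg_53
ICNWPYNGKSHFGAQWWFYNHSLDPLSDGCGP
>neg_54
LELHNSRRCGKASYMMSIQPVNKEVHHYAWKVGAGVPFVHEI
>neg_55
AFKGRTTDKYDEQARDSLWEFKPSSWWYGNNMVCYSGSWVTNGQKPWWRTLLPWVVSVYSFWPPKCWTMEVWKLGCYMLAIKEVDGLWLSVWIHEFLNKWNMDMHAGHWRGCSI
>neg_56
ELPSGRDYEQHVNCWMAGPPDMALGDKVSCHSKDKAKKGCKTSKLQSSGPRGFRQAQPANRYDPMGWSHPSNNDSLWGGVTNGMVWCDNTAADFCYVCGSWKEPVSSLGSGINDD
>neg_57
DHFYWQNFIRGGKKHCWPYFKPDHARWMKEDCAPCC
>neg_58
WSAISSPCGRHGTEPICTQESDATYEYWAYYIHCKVCRYDWWLPPVGLSCWKTCIKEINRTPTSCSNPFIHQGPYDNNKNLKLYPQAWSAHCG
>neg_59
FNACYKQCWGSSATETPNVIHWSWSVAGMIYKGEKLMQWWMSIYDEFHSFALEATSPNIGFWGYCCKCPICPMWSKYLPLLSTLCTALYNLDYIEHNHGKRGLEVAVLFISD
>neg_60
GVPEAREQCVKTHYEKANDGSMLWRDPNIMEWYYNRDCDQWLCGHLLPQKEFWTHAYCISVTEAWHMNEMESRFEDCYWEALKHYFVLCD
>neg_61
SGKPFFHACCHFGPDNKWSDYGSNDEPKWLCWMLEATLCTEANDDDEKHHSVVDFPKDWKPKPMAINVNNSYYTLDCKMPSKPQKMFEEHTLFWDACAMAMTTMQSIAHQFCE
>neg_62
SGHLSEHGYKHYAKNYYSHGNVELKADKSVLGCFEVYDYIEPYQPFLWHDSGKVIMFNQLHKIFWISQLNKMEWTFLWAMLWRWCCMQVMDAEPL
>neg_63
VHFVDLHVCDAKADKFEEYPQTSMAEERTCTKSPDMGPNCFHPWSSYKHDYTR
>neg_64
QFGQLLERGFGQHSCPGMEFVVDNREDGKVPDIHHGAMKANVWTQPYFDDIPTETQWDNEVYYTNVFIQAKSS
>neg_65
CLEVVTSLYKWPESEEPINDTMEAYLANKNSLHQSHFYAVKLAMYEMKTNTTKTVLRDP
>neg_66
IFNSAVWFQCSYPRDWESPTFMWIMCVCKPVWWLNPWDKSKLLKLRCYQAVNIAFDNAFFM
>neg_67
YIWTATSNMTGSFWCRSFTE
>neg_68
KPYWHQLHPWNPSHIAESNTTFTQTSVLWQIVSMAPISQKNCCCSEKTEEMWMWPMGEWLEYAWFKGDSMPFNQLMSKGHYNPDLQ
>neg_69
IWYLSSWDEIRIWSGCQCICSAMNWIVWADDTLTEKGDTPLWWECQPSVAHKPGGFPLIPQISGYHKHIKGERVYENLMWGWLIASWRLYVNLCKKYETEIVITCEFFF
>neg_70
WETYKINKTAIRTYLVLGDSYHACIYGWFVTYERIGENAFHDGLVATQIDFNDNKQNGVISQEDVVTGVECWIYDVVTTAAKFQVQPAKLGREFMLQNDHEVPGG
>neg_71
CFKSTYTFKQGNPHPRHDTCTELIAYMDDCACMGSRSADYFKYTEKQTKTQTIPWCYSFKMWGTMHEVQFRGTLDDKCRHQKQKAALVVDNLPKMSMLVHNETAAMAE
>neg_72
HDLCSIAKRNEAENDYTGDLTCTRAIESWYRYNIHHPYAFHFWCAYGDPSQWHISLKAELQCGCENSPSEIWCTSTGNPTANLDELSEMNETAPMEE
>neg_73
DLNSEHWKKCTQTGRHMRMWYLPLAQPTICPHMTMCLPQLTITLVDSDSPGYVAKMLLSWRKSFAKPEESCMCKLNLNKMHYKACFCVCVSQDCNSHTMECLYMVWSSHTRRWC
>neg_74
EAHHIMDVRHPFAHAETAYKQSCAGITTNHKDKAFWMGNDKSWDESWKMDGEMAKRFETHTATNHIKLKKVTVQSVHEPEYCQTPWLWFITLMPHPCHPNVFWMDMVL
>neg_75
LCWIGMEQLQTHYALFMVAPWCWKSFLVYYKATSMGKPYREDHESFFLEWVPYFKVGKYADARTCDHKVINVFGSATTFPTGWCMDYNAP
>neg_76
GHLHTMDGGYVGTENPYYGQWSAWPFHWPFAFMMSTFFYACAY
>neg_77
LGWCQNKKFAGEGCKKNAYGHKCKRNCICFRMDFPCHNEWQDLIFWHKIIMGKHTRHGDKENHHNCSWHSADQDLCGLYWHNSNDSCTVKHWTIHIV
>neg_78
SCHMMDAQDSHNPWYHDAPLTQTYTKKIMYGWDQDQKEEYCWVEFQYNWAFVNCQHIAHRWCCVQDKLGCVKGIFHHQWCDLSGVFGHDEY
>neg_79
ACWITSFQCKYICVEDYMWCEEWLKKQNKASGEMQKNWIDMKIPNCMCNCVCMCQLDENYGKADIDEWYYMRTWMDKAEPFDNWYQHKDIQHEDRVRQHECM
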