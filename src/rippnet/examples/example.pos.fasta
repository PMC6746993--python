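>pos_0
KHLCEWSKADGDRNWTYIMTPGTDSHHDDWTPNCCLGPYIHDNPLAPHTD
>pos_1
WWGCEWSKADEVDEFWECRCGHHVITIFFCMCCNYQNIVICNYGVM
>pos_2
YKLCEWSKADGVPNPYDLEWKRSGKKTFFTAKRPMLQHNYTAMSKWKLPRPGGSPYFKRVLQTPDMLWLVPLFRVYIHHAKMMWSQDKALITKGKERSHFLQLHPVFSAAMAQGNP
>pos_3
TQLCEWSAADGVVYKGARPSDTSPASLSSVWNQKWWKSFTICIPENQVQIRTGTS
>pos_4
RMLCEWSKADLVRPEQLVWLLMWSFEMHYWRVERVLSWRKLGFNYDTCHYWTMIHPHRDPPRWEVFFYHVLYWPFFGAPNSIDLICLNSMSNWDGTNGMC
>pos_5
FALCEWSKADGVEVASHKRPWMTPKGDVHYGPTTNCHWNHKHTLVISCLPHP
>pos_6
VYLCEWSSADGVHNVRVPSCAAYPGVDHTWSYGNGRNQNAPEYLCRRTIENWCTLYHDWDHKQVQVYLMWTDGKFMKHHMYHAGATFPDNFSQADHELMLTVWIFGWLILACCVCKHA
>pos_7
YTLCESSKADGVWNMFAWVSEEYYFYFVAVRNKIFTETQIDLNTMWCTTYARFDLKGYWQKELNVHCQPKFFKKYSEISIHQMNVCPANRKLGFWAMHSNTPKTTPWGQCQLQGTA
>pos_8
NELCEWSKADGVNAFFYPAMLFDVLMWATHHKY
>pos_9
QNLCEWSKADGVRPLKGILCMNSTWIGWIMEMQDARLEDLRYHHNQLTLNHIMCLLYSLDLWDLISCNMMGHKGERRMLYSCKEFMVYWKYYKSMQSWKNK
>pos_10
CGLCEWSKADGVLQHVMKGTVQQIIFVGMPQVLYNYNPTRDLV
>pos_11
SQLCEWSKADGVATMNLFRFCCYHEDIAC
>pos_12
VTLCEWSKADGVHYNIKSCENCRHFRIHMCEYRDCMSPNSDWNIMVHRMRLMVVQFQVGRGPQED
>pos_13
PDLCEWSKADGEYASDNNYIFWPPEWILTGFGKDRWVQENKMGYQHPWCSNRRSWAPCRDYWFVYAQYTVPQSHFMWLACQSVHHRHIPPRTAHKE
>pos_14
TFLCEWSKADGVERYFLDGANDRHYCHKKISQTYKIVKYCMTDGFFMTQMELNKAGHNMLHSCDWKEAEQACKDGLMTKFCWRFHTEPIMCHDMGIPIQDMTYMDAWTNH
>pos_15
ANLCEWSKAREVLCDGVKILHPIHQINGTCEAVPKCTVSEVCGEHDIHRQHWISNDVTMSRPIQVHD
>pos_16
HDLCEWWKADGVTFSAQDHHQRVCTCGTVDPVLTTIENFGLTDFECSLNWLKLFPLGTMIYPSYW
>pos_17
FHLCEWSKADGVPFPESDCVPPPGCSRSVKVNCWYCDQAHNSDQKRCCDSCCVAKIRPDPAWCESANDWNNQMIRFVHPKRGTKNQISRHCWIDKRGAKNYGSKGMHA
>pos_18
WCLNEWSKADGVKVQEYAKTWTIFQTAPGIRCCLNHVVGSDYVFRNKK
>pos_19
YVLCEWSKADGVESPYMSQREHSNVEEHIGQSLKPHPFQMDQADENVGAHKAEPVVNYNFCHRRCPRIWEELPWCSPMSQKGHMYELV
>pos_20
TKLCEWSPADGVAYHTYLGEKEATMDTTAIISPGTDWHNCACNMVPCVESACDEDNFGQKMLYQKYPPDTL
>pos_21
DMLCELSKADGVRQKIWPLTSPLCQSIT
>pos_22
ISLCEWSKADGVHSNHYGLEIHSVLGCHAYEPGIQQEHNKRDFIAVIIWTWAQDNMHHGVTRIDSFAGEKQNFLHCDCECWVC
>pos_23
HYLCEWDKADGVAHGIWGWPPNKTIDSTAKAMMQRWNCKTE
>pos_24
EMLCEWSKEDWVFKFMPQWKV
>pos_25
IILCEWGKADGVKTNSMESNQLNTDQNWYFECVKKNPRFEGVLAHGWERPTMAKWSTECFPQLEIMCIHCIHQAHCIRIWIPLSFDHNFNYEHAHW
>pos_26
HAPCEWSKADGVYKTADYILQKGILCIYN
>pos_27
NMLCEWSKADGVNNVMLMWMTSTIAQQRWMYRFIQYLRWV
>pos_28
EQLCEWSKADGVGYEASECFHIMDSSEPNRHQGTFDHTDSGNQSAYDPKSRWNYHSSGSTPSCCAFEQPETCLGQEHFYANQYGNFAEGDHEERMSFYL
>pos_29
FMWCEWSKADGVKKTYNMMIWSVCKSEWWLHPSTGYFGYVSKPEHPCYCFQVHRSNTGNWQKVNYGFWESKPHCYDQIDMDFWQ
>pos_30
IQMCCWSKATGVKEFTGHHGNVSEFLYENSVWTYPCIEDQLEHEHLLKIQKYSQRLMTEEGEAEYCFNFNKENLEMYHPATAAMVKGGILQTHDALENQYAH
>pos_31
QPVNEWSKADGVEMVAWYTFPYQKIQPNSWQPKDHVMFTVEYWTCRWFWILKLNPTHENIGEQVGGCMWEGNDWNCPKASFGCGTYYWMMQWM
>pos_32
MMLCEWSKADGVICQQSEWRFPMCDCYCVMFCIIYIYQWNEFTNLYGYHHFNKNMAPSTIEETKCGKAKREYQEMVCAPQDETVKQP
>pos_33
NKLCEWSKADGVHDGSNHQEIFQHC
>pos_34
IELKEWSKADGVRGCITQLEDPIPAFRINSCLHAE
>pos_35
MWLCEWQKADGVVVIYWCMAIGVTHAYRFSLQMC
>pos_36
LPLCEWSKADCVEDTQEHFSYCCWTGMAAHGEYVWYIRFEWDHYYKCVCEQIVRENMEDICLLMLWNRYQCNKWLFYSPVGAEMGCEFLFANKYNCLLWKSNQDFDELTPNTRNMGVM
>pos_37
KFLCEWSKEDGVGDMSDMKLDYYLSAHIPHNLQLTVSWNRVVNYTRRFNIIQVLKFTIWAVIRTINCNPHANFTMTQSFPVLVSSPSNLNGPRGLVYFNENWAYTIGIYTEDAGCKVQN
>pos_38
YHDCEWSKADGVQRHWTSPSHQWSPKMARGSTVENHSTGYMLQCMADSWPTSMGERFMSPQTYVYLLWSNRYQVFY
>pos_39
DPLCEWSKADNVASYAHFKMSINYH
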