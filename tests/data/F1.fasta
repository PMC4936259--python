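>query
QPGGIGRSLFLRLACITKNMVISNVVTIYFSALAVMIIPHEIAFTSPLYTFKVSIASAKC
GSVAGQIYDDRQVAALLVRIKCLFCLEQEMNWKSAPYIVNDEGVSALEFLEQAAGVIRNK
HAPDFWFTQGIGQIIYPLAAVVYLNPWGHQPHVYYQSVNV
>sub0_seq1
GPDHYDKPESENAYLFDAGTRGTQRVQEIIHCSFGPNPHHKYKKKCFIYYYFWHQTGILA
KVPVVDGRKSLEGLVLLLRIKCEFCCEQEMNWKSAPYMVEMIKIAAVLDPTIKVVVIRNK
HATDFWGIQGIGQAIYPLGAVVYLNRTKGLIFRFRPGSGT
>sub0_seq2
FKEAAIKELPHLEIIPSGPFVISNGVTIYFSALAVMIIPHLIAFTSPLYTFMVSIFEQDV
DPEPVTNLKQRPLRHLLVRIICLFCFEQEMNFKSAAKAVEEVTDDFRCMQVWKTYLFYRK
YIPLSRLFGVCKHPGVHGITNGLNDKFKEAHPFDRATAFK
>sub0_seq3
EIRDADQWKKCDELGHNVCDVISNGVTIYFEQLAKMIAPHLIAFTSPLYTMGVSINYIEV
AYVHLDNATDVFIAIALVRKKCLFCCEQEMNWKSAPYAVELQMEAQVLVYLGEMVVIYNK
HAPDFDIIQGIGQAIYPLGAVVYLDLLGAGIGIHIFCDKQ
>sub0_seq4
MELLQQGSLAKEPQPHFCHLVSSNGVTIYFSQLAVMIIPHLIAFTSPLYTFMVSINNQTT
KARGLGEEPLERSQMLLVRIKCLFCMEQEMNWKSAPKAVEVESTYIIQGRVLMFEVIRNF
IAPDFWIIQGIVQAIYPLGAVVYLNALAPMTGSLEPNYRR
>sub0_seq5
VCIVPAEQTMDAYSTQGDSLVISPGVTIYFSQLAVMIIPHLIAITSPLYTFMVSISGGGI
STPIWETTRVATLTDLLVRIKCLFCCSQEMNAKSAPYAVELDVGSWRRLMLAAPEVIRNK
HAPIFWIIQGIGQATYPLGAVVYLDIADEEFVSLTSFKMS
>sub1_seq0
PAVRKPITEINRDKLSETLNVISNVVTIYLSQLAVMIIPHLIAKTSPTYTFMRSIAIRPR
LVIGTEIYVKKSIAEQTADVPPPGLLVKRIVTYFTLLLCTGTPHLKAYDLRRGQFVIRGK
HAPDFWIIQGIGQAIYPLGAVRYLNTHKLVLLWIPVSDYA
>sub1_seq1
FSECLSCLGTAEGLMQAKVLDISNGVTIYFSQLAVMIIVHLIAFTVPLYTFMVVIIVSGN
PVPKSKQDGESVAITQAALVTPPGLLVKRIVTYFTLELCTVYKLRAGKSNRGYSNSIRGK
HAPSFWIIQGIGQAIYPLGAVVYLNVYAFTLAHADPVHGR
>sub1_seq2
TAVFAANSSKRQHLSYAQSAVISNGVTIYFSQLQVMIIPQLIAFTSGVYTFMVSIEFGAG
IFGVAGGTLAQAEPRQAADVSPRYLEVKRIVTYFTGLLCTAAFTLSVTKNGFSKGVARHK
HAPDFWIIQGIGQAIYPLGAVVYLNETDCGAVVVTYWDRL
>sub1_seq3
WEEKEGKSRNVLSCVDAYVLGISNGVTIYYTQLAVMIIPGLIAFDSPLYVFMVSISLLEH
KLFIPKGYIERIQLCQAADVSEPGLLVKKIVTYFTLLLCTQTLSAFEEVASTETVVIRNK
HAFDFWIIQGIGQAIYPLRAVVYLNNKARTAAEYELWTSC
>sub1_seq4
LRDIDGRPAGLLVINLQANYVISNGYTIYFSQLAVMIIPHLIAFTSPLYTFMASIAPNEQ
CESEAITVWHDHDADQADDVSPPLLLVKSIVTYFTLLLCTATFVATMIFRDCELDVIRNK
HAPDFEIIQGIGQAIYPLGAVVYLNKKSIAFFRDSLIAGV
>sub1_seq5
EDTSEYISLYVYDAICTANFVINNGVTIYFSVLAVMIIPHLIAFTSPLYPFMVSIQEWLK
VKWGVLNEETLKKWDLAADVFPVGLLVKRIVTYFDLLLCTTVHSAYYIFTSGATGVIRNK
HDPDFWIIQGIGNAIYPLGAVVYLNRINWGKLDVNIIDDE
>sub2_seq0
VILWGKMYGALEHEYVYLSYVIHNGVTIYFLSVAVAIIPHLIAFTSPLYTFMVSHGQGHV
SDYYGGPKNEFEIDSNDRDIPKANIIEEYNNSIENIICKAELIALAEEHEAGSMHVIRNK
EAPDFWIIQNIGSKIYPLGAVVYLNAPSRPEFYHVEKTAY
>sub2_seq1
PLDMSAMSAWKNPSIDSENAVISNGVTIYFSQLAVMTIPHLIAFTSPLYTFMVPIRVARD
GEKEPSKRELAMQTENDRDIPKANIIEEYNNSTENIGCKAYRSHLGFVTAGGSVRVIRNK
HAPDFWIIQGIGQAIYPLGAVVQLNKQYNFAVWIAIYMDI
>sub2_seq2
YRMALFIGYTPVAESNPSNKVISNGVTIYFSQLAVMIIMSLIAFTSPLYTFMVSIGVRRG
GAFDAASAQGGCNTFNDRDIPKANIISEYGVSIENLICKAFDRKGAFAAKFFILLVIRNK
SAPDFWIIQLIGQAIYPLGLVVYLVMTQHYNAFFIDREFR
>sub2_seq3
INLLEYSASFRIEQPRLLFPNISNGVTIYFSQLAVMNIPRLIAFTSPLYTFMVSIWIGTL
SSPEEKAIRQSVRRKEDRDIPKACFIEEYNNSIENGICKAVRNALITHRGDLFEEVIRNQ
HTPDFWIIAIIGQVIYKLGAVVALNMGYLVQAFNQLRGKP
>sub2_seq4
SACPDDAHTVSLNPADPQRSVISNGVTPYFSQLAVMASPHLIARTSPLYTFMVSIAPGPF
KTPAQLGIGIRCRVTNDRDIPKANIIEEYNNSIENIICKAPVVLIKVIKLNPIKLVPRNI
HAPDFWIIQGIGQAIYPLGAPVYLNTQLWIAIYLSETELL
>sub2_seq5
FTILDDDKWLNKRAKIHVQQVISNGVTIGFSQLAVMIIPHLIAFTSPLYTFMVSILSQAV
KPVDCVGVESSSLMENDRDIPKANIIEEYQNSISSIILKASLRDHGFSLDITVLCVIRNK
HAPDFWIIQGIGQAIYPLGAVVYLNNNKRATFGAAEQQFS
>unrelated0
DLLLATLANNNAMNLVDSQVAFHREPRRAYKNVGIITEDSVKGVSFCAYEWWIKPNSITK
IEQDMGAKSSGAVSQILKEFEHLLDKDADREEQGALHNQFTGARTSDTIAEEGQVGKKAG
GLSRSAPVGLASLGSQRLSTGQASTFSHVLNMAANNACED
>unrelated1
KNESPATVLCNDPNLGSPRFNFDDIVDEDNGGTEEDCMSRTKMESAIGSCMVVYRKSIRR
LGYFIDYDVPGQSRDAVHVGNFRGWHTKQCITPLIQIGAIEASKHFANERIAMENIVTLT
RIHLSFKSKNTATTFAKGVQVMQSSHGRMFEVAAEIDEGV
>unrelated2
AHINQRDGTAEMDSGIRSEANFSLTGSVFDRNAESAPFAANRDNSATVTRVKKNKVAKLQ
ALKPAGVGSGMRVIKEYADGRLGFKSYRIGDDFWHSVGYDQKCYGGGKLMEPAGNGDNKM
LDESMLMSAMNKYDGFVLLVSEKNEFLKTYLFDTMSLGKD
>unrelated3
KGTGTDERVQCCEASRDAESLDGNEQWAEMINKQQVDWQTAVRVVEEFAYPPDQFDKVAK
NGTGAAVAWVEKYLEKRQLTVSDLETVSQYSESESILYAEKIFDLGSYICKEYSDDLLAR
KFVQEYCCTLYVAGKAYKRVHYLRRAEPGLYWDVPQDAAD
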