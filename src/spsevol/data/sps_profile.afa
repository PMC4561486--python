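>Ecoli_SelD
LQSCPDQPGWFYRQHIWAYDMNKAHCCHHDGWVQLQCGPTGKWDSRVLLASAWWMRKAGCUKIAMFVINYYFFCFSETSSGDKCEIPHCWNDVKEEEIKGKVQETCDHNDHSLMCEWVVP
>Hinflu_SelD
LQSCPDQPGWFTRQTIWAYDMNKAHCCHHDTWVQLQCGPTGKWQSFVLFASAWWHRGAGCUKIEMFVIWWYFFCFSETSSGDKCEIPICWNDDKEEEIKGKVLATCDHNDHWLMCEWVVP
>Mjann_SelD
LGSCPDQNGWFTIQHIWAKDMNKGHCCHHDTWVMLQYGPTGKWDSFVLFAWAWWHRGAGCUKIEMNVIWWYFFCFSETSSERKCEIPICWNDVKEEEIKGKVQATCDHNDHSLMCEWVSP
>Drerio_SPS2
LQSCPKIPGWFLRQHIWACDMNKALCCHHDTWVQLQCGPTGKWDSFVLFASAWWHRGAGCUKIEMFVIWHYFFCLSETSSGFKCEIPIFWNDVKIEEIKGKVQATCDHNDHSLMCEWVVP
>Hsap_SPS2
LQSWPDQPGWVGRQKIWAYWMIIAHYMHHLTYEYLQQGPTGKWDSFVLFASAWWHRSAGMUKIESFVIWWYFFCFSETSSGDKCEIPNCWNDPKEEEIKGKVQATCDHGDHSLMCEWVVP
>Dmel_SPS2
LQSLPDQPGWETRQHIWAYDMNPAHCCHHDPWVQLQCGPTGKWDSFVLTASAWWHRGAGGUKIELFVIWWYFFCFSETSGTFKCEIPICWNDVKEQEIKGKVQATSDHNDVELMCEWVVP
>Cint_SPS
LQSCPDQPGWFTRQHIWAYMMFKAHCCHHDTWVQLQCGPTGKWDSSRLFASAWWCRGAGCUKIEMFVIWWYFFCFSETVSGDDCEPPIPWNDVKETEIKGKVQMLCDHNDHSLMCEWVVP
>Dwil_SPS_Cys
LQSDPDQPGWFTRQHIWAYDMNKAVCCHHDWWVQLQCGPHGKWDSFVRFDSAWWHRGAGCCKIEMFVIWRYFMCFSETSSGDKCEIPICWPDVTEEEIKYKVQTTCDLNDHSLMCVWVVE
>Cele_SPS_Cys
LQSLPDQPGWFTRQHIWAYD----HCKHNDTWVQLQSGPTGKWDSKMCFASAWWSIWAGECKIEMFVIWWYFFCFSCTSSGDKCEIPICWNDVKEEEIKGKVYATCDHNDHSLSCEFVVP
>Gmax_like_Cys
LQSCPDKQGWFTRQNHWMYDMNYAHCCHRDTWVQLQCGPTGKWDYFVLFASAWWHRGAGCCKIEMFVIWWYFFAFSDTSSGMKCEIPICWNDVKE---DGKVQATCDQNDHSLMCEWVVP
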