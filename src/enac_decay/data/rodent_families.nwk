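(((Graphiurus_murinus,(Muscardinus_avellanarius,Glis_glis)),(Aplodontia_rufa,(Xerus_inauris,(Spermophilus_dauricus,Ictidomys_tridecemlineatus,Cynomys_gunnisoni,Urocitellus_parryii,(Marmota_himalayana,(Marmota_marmota,Marmota_monax)))))),(Pedetes_capensis,((Castor_canadensis,Dipodomys_ordii),(((Jaculus_jaculus,Allactaga_bullata),Zapus_hudsonius),(Nannospalax_galili,(Cricetomys_gambianus,((Microtus_ochrogaster,Cricetulus_griseus,Mesocricetus_auratus,(Peromyscus_maniculatus,Peromyscus_leucopus)),((Rattus_norvegicus,Rattus_rattus),Grammomys_dolichurus,Mastomys_coucha,(Mus_musculus,Mus_caroli,Mus_pahari)))))))),(Ctenodactylus_gundi,(Hystrix_cristata,(((Heterocephalus_glaber,Fukomys_damarensis),(Petromus_typicus,Thryonomys_swinderianus)),(Erethizon_dorsatus,((Chinchilla_lanigera,Dinomys_branickii),(((Cavia_porcellus,Cavia_tschudii),Hydrochoerus_hydrochaeris,Dolichotis_patagonum),(Dasyprocta_punctata,Cuniculus_paca),((Octodon_degus,Ctenomys_sociabilis),(Capromys_pilorides,Myocastor_coypus)))))))));
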