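y	ra	rb
1	0.472331250490292	0.609261258544444
1	0.714237402608	0.598511851954087
1	0.634927507122026	0.695383370357938
1	0.836648184651096	0.895323138127916
1	0.806352401596303	0.545451735794506
1	0.536436993083222	0.85228055644776
1	0.860443566555314	0.638402167572775
1	0.799990140968504	0.446060496261617
1	0.826466792125441	0.670389919174767
1	0.652072359542929	0.613677643691945
1	0.884986324428068	0.9620738884299
1	0.857389740809675	0.689663763537367
1	0.681128053923867	0.616059201711974
1	0.25643269336238	0.286888882684171
1	0.938100654542044	0.708427260470913
1	0.737750548930743	0.604740997842518
1	0.536314353435528	0.750334582704323
1	0.81110458527588	0.937408973284162
1	0.732807737316507	0.857496027280864
1	0.760823750539248	0.858473339389981
1	0.803575661295894	0.511579850394905
1	0.832464350505991	0.850228996485898
1	0.603268863142607	0.668338260984174
1	0.247808008961151	0.131539942828435
1	0.748858481969912	0.780522465260144
1	0.835828919861988	0.579158295943866
1	0.73156126002245	0.826093842029369
1	0.446291692716392	0.265940589492167
1	0.625730261764545	0.462306790335524
1	0.886856834849434	0.497469356163658
1	0.863044633095834	0.760154103585952
1	0.614528940765059	0.676982033181298
1	0.870322443257092	0.53175829532788
1	0.603685859775983	0.752504673835756
1	0.3360939468534	0.212035059162007
1	0.54701109978448	0.352656112348982
1	0.56112119507442	0.801604398584148
1	0.645914778822122	0.408960080971332
1	0.895399301625345	0.812995819164895
1	0.813741993063557	0.653179496959631
0	0.397114575480261	0.556953571842375
0	0.603042327485914	0.768361368671555
0	0.643290267196377	0.843888353855256
0	0.614646197460545	0.517310997888335
0	0.323255435252193	0.0960902345707913
0	0.413100666666596	0.828300787606473
0	0.581223928468679	0.679701881637185
0	0.679116778716243	0.709752358484121
0	0.388605802198668	0.480478092490163
0	0.672380734345483	0.718442983324803
0	0.605440442920585	0.526814963123443
0	0.287721981983174	0.492335570061716
0	0.647225971464462	0.471150683415624
0	0.131408728883712	0.145072362686768
0	0.83009527323765	0.838902515784223
0	0.770683561625784	0.917134548299768
0	0.373387975655616	0.385249494513419
0	0.212775712798378	0.163951965097557
0	0.560618414957529	0.701745744294278
0	0.459215070745158	0.470833132993022
0	0.809140967890492	0.513595630513874
0	0.633915539346802	0.494540588499878
0	0.464373760878992	0.4774162142072
0	0.449234763171566	0.436353750539289
0	0.213957534248553	0.202422515489284
0	0.453480628323165	0.825748257725528
0	0.318347736029113	0.206217049972549
0	0.813702910754079	0.400092954457344
0	0.379917849321009	0.56210432171504
0	0.79450684926301	0.819669143407607
0	0.668321469099902	0.376752404900027
0	0.327563369280409	0.0608190904116959
0	0.611041486223359	0.463577243818745
0	0.198009983980057	0.474010327208782
0	0.119480009824775	0.31003436175958
0	0.438771362531378	0.524062584099332
0	0.514176831265239	0.545543775937087
0	0.423229953926193	0.279185839554434
0	0.350265563728056	0.715454824772063
0	0.585434752953689	0.411446752282876
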