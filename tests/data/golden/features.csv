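ces_x,ces_y,des,ta,icpcv_lx,icpcv_ly,icpcv_rx,icpcv_ry,target_x,target_y
319.9505761372196,210.02760290704188,40.657416524223336,-0.7416030769852894,-39.16759198726419,-6.983891152832797,20.02630194994248,-6.494836951007244,192.0,108.0
319.6985866530662,209.77642232840222,39.81366286319049,1.9055984076752839,-39.55257963980097,-4.501358305419274,20.57731167166338,-5.758673937352427,192.0,108.0
319.5467466626138,209.86108414306744,40.69853500103451,0.21827305677193876,-38.458839118159574,-5.853991151906399,20.36116140755803,-6.43923987522416,192.0,108.0
320.19487755713055,210.15050520310496,40.45743332498074,-0.9412640297654565,-39.219656991332045,-6.896701707596577,19.837749775428733,-6.068935304878238,192.0,108.0
319.8277083592371,209.49015517166913,39.289242116213615,1.1919757337547279,-30.366879833835014,-5.095460484550699,30.83214716908668,-5.955109167730797,960.0,108.0
320.07209147204094,210.20308342950085,39.82442462300129,-0.8464222408278227,-30.225740209259072,-7.31308336598687,30.541085218921296,-5.69218319842463,960.0,108.0
320.72428464079223,209.5808397597923,39.89518719595147,-0.4262779482800183,-30.232525853607115,-6.154913272807477,29.046047368947598,-5.804870837257823,960.0,108.0
319.4734864356446,210.19784447692535,39.907264323621426,1.9321325240887075,-30.013158083502788,-5.983563313617793,29.408662452396868,-7.213322338641348,960.0,108.0
320.0412015121126,209.2581843551921,40.43501464442397,-0.02313639372785168,-20.334855496015678,-5.5823773939611385,39.031674453798416,-5.494088111655714,1728.0,108.0
320.1112252055775,209.65996023710187,41.314394464859426,-0.37379583160595437,-19.877808386443917,-5.914776202773481,38.816545715486825,-6.170381167231682,1728.0,108.0
319.71490161275744,210.117684082932,40.63863587058764,0.8362819552018482,-18.875735009192795,-6.4854023223420825,39.99173595706151,-6.911799641113333,1728.0,108.0
319.8097803966393,210.2343294027711,40.67633031107305,-0.0839213828467067,-19.889887653374615,-5.894444443756981,39.48555773041835,-6.6710084260408,1728.0,108.0
320.27390228543067,210.12985106567805,39.861379037422196,3.8000369312281133,-40.378069734081635,2.0702676119606735,20.217403367807435,-1.1285835116894987,192.0,540.0
320.75510987351174,210.4415507533698,40.50721734222915,-0.1623898346019453,-39.79451930125214,-0.1872426537860008,19.03586800934164,-0.06918176478285432,192.0,540.0
319.56207320206977,209.63605577106176,39.00237013135147,-1.2705609529012174,-38.51654085209128,-0.62250422483325,22.454255904683464,0.6811433458314582,192.0,540.0
320.22399235891277,209.6825966753902,40.74123511405071,0.043051595887518404,-39.65812109410086,0.5452061012712477,19.334414350651798,1.325449607442721,192.0,540.0
319.43546541239925,210.18548092372572,40.02945681318432,-0.027753430700059506,-29.6625246396531,0.14117496756020387,30.15928544028185,-0.45263162767511744,960.0,540.0
319.82614885780947,210.1048104838702,40.00563237690184,0.5075423435694818,-29.775617506689343,-0.7696635425367617,29.61377426158913,-0.20143693326718903,960.0,540.0
319.9800475269077,210.07375871529445,39.67985522816861,-1.495948942892715,-30.486140141538954,-0.23872389480436595,30.041654090325665,0.8500957662841984,960.0,540.0
320.57509928575325,210.7708756498211,41.222785990109436,0.8103511358757437,-29.551104736024968,-0.3879679035159427,28.10495831370116,-1.3977387849983813,960.0,540.0
320.26178084658676,210.34800816419374,41.39993314224583,-0.014953535465917227,-19.630276603845175,-0.5355978384943967,38.22933603697936,-1.2687988505666397,1728.0,540.0
320.31425358576746,210.3694024002021,40.16168834254566,-0.46158500326190716,-20.96974950402779,-0.1855941090093154,39.13415977824263,0.1690272797647765,1728.0,540.0
320.00351067984064,209.77424044680674,39.39578689207929,-0.44191512057930854,-20.62910128914649,-0.822875590752318,39.36031970190072,-0.2444785868511019,1728.0,540.0
319.97899684361266,210.39370322608724,39.36880180206327,-0.0992203792588799,-20.978175161439538,-0.32916043220106417,40.20554203645946,-0.4928055916968219,1728.0,540.0
319.21424483319674,210.4198586582851,40.2315649297049,0.21994536872118176,-38.43124684516022,6.505653718592811,20.440386081221334,5.7740991134744775,192.0,972.0
320.3166893897224,209.77069684124322,39.866662966615635,-0.9660719288973499,-39.02379600460068,7.179746002162716,19.93282910280203,7.457361711750707,192.0,972.0
320.0131277437408,209.9628618377733,41.693519123880975,-0.8008554629795995,-39.140220490310924,5.452091117571086,19.63137249600419,7.04856035732405,192.0,972.0
320.21240096519705,210.43210139503802,39.42920296531949,-0.31833995810282917,-39.616056648592576,4.943181424602557,20.220819972679124,6.009532432202803,192.0,972.0
320.1900920284662,209.29338489274443,40.65522237994836,-0.8046124476700499,-29.433985213359392,6.875865510566285,28.89405053937145,7.09104252253988,960.0,972.0
319.8361518265857,210.21126691755978,41.2065868185114,-0.13782264800308852,-28.2127211905472,6.830701102715835,29.0867174705279,6.4318838011979835,960.0,972.0
319.99954485900844,209.2122715487249,40.420829630389385,2.0833976781860026,-29.802023252374454,7.664639621451244,29.60106410888767,6.495703917260926,960.0,972.0
320.1617762457047,210.34044227143443,40.09527038310408,1.0113587994137394,-29.498737689916766,6.608287491861802,30.70876635157458,5.889952740754637,960.0,972.0
319.8566010431075,210.20526868910417,40.18972363171757,0.12811316836500114,-19.999356895094365,6.289374263922014,39.90621235945855,5.291770592777198,1728.0,972.0
319.55714729182097,210.33809672848736,40.14473449925723,1.7984044129892303,-19.291311403620682,6.550575183812015,39.096674613390576,4.3229339484249465,1728.0,972.0
320.02051931599823,209.4571371004904,39.27289592515509,0.8291666524177199,-20.928794498438037,7.301271140064955,39.61933026113252,7.058274297893263,1728.0,972.0
319.5536316020974,210.68541128294493,40.05165682189792,-1.5462517985850408,-19.447554657045714,5.90027074718239,39.25050731214674,6.017728110335298,1728.0,972.0
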