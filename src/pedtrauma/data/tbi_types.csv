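code,tbi_type
80000,type2
80001,type3
80002,type2
80003,type1
80004,type1
80005,type1
80006,type2
80009,type2
80010,type1
80011,type1
80012,type1
80013,type1
80014,type1
80015,type1
80016,type1
80019,type1
80020,type1
80021,type1
80022,type1
80023,type1
80024,type1
80025,type1
80026,type1
80029,type1
80030,type1
80031,type1
80032,type1
80033,type1
80034,type1
80035,type1
80036,type1
80039,type1
80040,type1
80041,type1
80042,type1
80043,type1
80044,type1
80045,type1
80046,type1
80049,type1
80050,type2
80051,type3
80052,type2
80053,type1
80054,type1
80055,type1
80056,type2
80059,type2
80060,type1
80061,type1
80062,type1
80063,type1
80064,type1
80065,type1
80066,type1
80069,type1
80070,type1
80071,type1
80072,type1
80073,type1
80074,type1
80075,type1
80076,type1
80079,type1
80080,type1
80081,type1
80082,type1
80083,type1
80084,type1
80085,type1
80086,type1
80089,type1
80090,type1
80091,type1
80092,type1
80093,type1
80094,type1
80095,type1
80096,type1
80099,type1
80100,type2
80101,type3
80102,type2
80103,type1
80104,type1
80105,type1
80106,type2
80109,type2
80110,type1
80111,type1
80112,type1
80113,type1
80114,type1
80115,type1
80116,type1
80119,type1
80120,type1
80121,type1
80122,type1
80123,type1
80124,type1
80125,type1
80126,type1
80129,type1
80130,type1
80131,type1
80132,type1
80133,type1
80134,type1
80135,type1
80136,type1
80139,type1
80140,type1
80141,type1
80142,type1
80143,type1
80144,type1
80145,type1
80146,type1
80149,type1
80150,type2
80151,type3
80152,type2
80153,type1
80154,type1
80155,type1
80156,type2
80159,type2
80160,type1
80161,type1
80162,type1
80163,type1
80164,type1
80165,type1
80166,type1
80169,type1
80170,type1
80171,type1
80172,type1
80173,type1
80174,type1
80175,type1
80176,type1
80179,type1
80180,type1
80181,type1
80182,type1
80183,type1
80184,type1
80185,type1
80186,type1
80189,type1
80190,type1
80191,type1
80192,type1
80193,type1
80194,type1
80195,type1
80196,type1
80199,type1
80300,type2
80301,type3
80302,type2
80303,type1
80304,type1
80305,type1
80306,type2
80309,type2
80310,type1
80311,type1
80312,type1
80313,type1
80314,type1
80315,type1
80316,type1
80319,type1
80320,type1
80321,type1
80322,type1
80323,type1
80324,type1
80325,type1
80326,type1
80329,type1
80330,type1
80331,type1
80332,type1
80333,type1
80334,type1
80335,type1
80336,type1
80339,type1
80340,type1
80341,type1
80342,type1
80343,type1
80344,type1
80345,type1
80346,type1
80349,type1
80350,type2
80351,type3
80352,type2
80353,type1
80354,type1
80355,type1
80356,type2
80359,type2
80360,type1
80361,type1
80362,type1
80363,type1
80364,type1
80365,type1
80366,type1
80369,type1
80370,type1
80371,type1
80372,type1
80373,type1
80374,type1
80375,type1
80376,type1
80379,type1
80380,type1
80381,type1
80382,type1
80383,type1
80384,type1
80385,type1
80386,type1
80389,type1
80390,type1
80391,type1
80392,type1
80393,type1
80394,type1
80395,type1
80396,type1
80399,type1
80400,type2
80401,type3
80402,type2
80403,type1
80404,type1
80405,type1
80406,type2
80409,type2
80410,type1
80411,type1
80412,type1
80413,type1
80414,type1
80415,type1
80416,type1
80419,type1
80420,type1
80421,type1
80422,type1
80423,type1
80424,type1
80425,type1
80426,type1
80429,type1
80430,type1
80431,type1
80432,type1
80433,type1
80434,type1
80435,type1
80436,type1
80439,type1
80440,type1
80441,type1
80442,type1
80443,type1
80444,type1
80445,type1
80446,type1
80449,type1
80450,type2
80451,type3
80452,type2
80453,type1
80454,type1
80455,type1
80456,type2
80459,type2
80460,type1
80461,type1
80462,type1
80463,type1
80464,type1
80465,type1
80466,type1
80469,type1
80470,type1
80471,type1
80472,type1
80473,type1
80474,type1
80475,type1
80476,type1
80479,type1
80480,type1
80481,type1
80482,type1
80483,type1
80484,type1
80485,type1
80486,type1
80489,type1
80490,type1
80491,type1
80492,type1
80493,type1
80494,type1
80495,type1
80496,type1
80499,type1
8500,type3
85011,type2
85012,type2
8502,type1
8503,type1
8504,type1
8505,type2
8509,type2
85100,type1
85101,type1
85102,type1
85103,type1
85104,type1
85105,type1
85106,type1
85109,type1
85110,type1
85111,type1
85112,type1
85113,type1
85114,type1
85115,type1
85116,type1
85119,type1
85120,type1
85121,type1
85122,type1
85123,type1
85124,type1
85125,type1
85126,type1
85129,type1
85130,type1
85131,type1
85132,type1
85133,type1
85134,type1
85135,type1
85136,type1
85139,type1
85140,type1
85141,type1
85142,type1
85143,type1
85144,type1
85145,type1
85146,type1
85149,type1
85150,type1
85151,type1
85152,type1
85153,type1
85154,type1
85155,type1
85156,type1
85159,type1
85160,type1
85161,type1
85162,type1
85163,type1
85164,type1
85165,type1
85166,type1
85169,type1
85170,type1
85171,type1
85172,type1
85173,type1
85174,type1
85175,type1
85176,type1
85179,type1
85180,type1
85181,type1
85182,type1
85183,type1
85184,type1
85185,type1
85186,type1
85189,type1
85190,type1
85191,type1
85192,type1
85193,type1
85194,type1
85195,type1
85196,type1
85199,type1
85200,type1
85201,type1
85202,type1
85203,type1
85204,type1
85205,type1
85206,type1
85209,type1
85210,type1
85211,type1
85212,type1
85213,type1
85214,type1
85215,type1
85216,type1
85219,type1
85220,type1
85221,type1
85222,type1
85223,type1
85224,type1
85225,type1
85226,type1
85229,type1
85230,type1
85231,type1
85232,type1
85233,type1
85234,type1
85235,type1
85236,type1
85239,type1
85240,type1
85241,type1
85242,type1
85243,type1
85244,type1
85245,type1
85246,type1
85249,type1
85250,type1
85251,type1
85252,type1
85253,type1
85254,type1
85255,type1
85256,type1
85259,type1
85300,type1
85301,type1
85302,type1
85303,type1
85304,type1
85305,type1
85306,type1
85309,type1
85310,type1
85311,type1
85312,type1
85313,type1
85314,type1
85315,type1
85316,type1
85319,type1
85400,type1
85401,type1
85402,type1
85403,type1
85404,type1
85405,type1
85406,type1
85409,type1
85410,type1
85411,type1
85412,type1
85413,type1
85414,type1
85415,type1
85416,type1
85419,type1
9501,type1
9502,type1
9503,type1
99555,type1
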