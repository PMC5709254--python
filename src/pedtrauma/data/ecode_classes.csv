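code,category,group
E8106,bicyclist,traffic
E8107,pedestrian,traffic
E8116,bicyclist,traffic
E8117,pedestrian,traffic
E8126,bicyclist,traffic
E8127,pedestrian,traffic
E8136,bicyclist,traffic
E8137,pedestrian,traffic
E8140,excluded_occupant,traffic
E8141,excluded_occupant,traffic
E8142,excluded_occupant,traffic
E8143,excluded_occupant,traffic
E8144,excluded_occupant,traffic
E8146,bicyclist,traffic
E8147,pedestrian,traffic
E8156,bicyclist,traffic
E8157,pedestrian,traffic
E8166,bicyclist,traffic
E8167,pedestrian,traffic
E8176,bicyclist,traffic
E8177,pedestrian,traffic
E8186,bicyclist,traffic
E8187,pedestrian,traffic
E8196,bicyclist,traffic
E8197,pedestrian,traffic
E8206,bicyclist,nontraffic
E8207,pedestrian,nontraffic
E8216,bicyclist,nontraffic
E8217,pedestrian,nontraffic
E8226,bicyclist,nontraffic
E8227,pedestrian,nontraffic
E8236,bicyclist,nontraffic
E8237,pedestrian,nontraffic
E8246,bicyclist,nontraffic
E8247,pedestrian,nontraffic
E8256,bicyclist,nontraffic
E8257,pedestrian,nontraffic
E8260,pedestrian,pedalcycle
E8261,excluded_cyclist_only,pedalcycle
E8262,excluded_cyclist_only,pedalcycle
E8263,excluded_cyclist_only,pedalcycle
E8264,excluded_cyclist_only,pedalcycle
E8268,excluded_cyclist_only,pedalcycle
E8269,excluded_cyclist_only,pedalcycle
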