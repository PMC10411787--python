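specimen_id,subspecies,habitat,mobility,sex,limb
DPpha 35,caribou,mountain,altitudinal,male,hind
DPpha 36,caribou,mountain,altitudinal,male,hind
DPpha 37,caribou,mountain,altitudinal,female,hind
DPpha 38,caribou,mountain,altitudinal,female,hind
DPpha 39,caribou,mountain,altitudinal,female,hind
DPpha 40,caribou,mountain,altitudinal,unknown,hind
DPpha 41,caribou,mountain,altitudinal,unknown,hind
DPpha 42,caribou,mountain,altitudinal,unknown,hind
DPpha 43,caribou,mountain,altitudinal,unknown,hind
DPpha 44,caribou,mountain,altitudinal,unknown,hind
DPpha 45,caribou,mountain,altitudinal,unknown,hind
DPpha 46,caribou,mountain,altitudinal,unknown,hind
DPpha 47,caribou,mountain,sedentary,female,hind
DPpha 48,caribou,mountain,sedentary,unknown,hind
DPpha 49,caribou,mountain,sedentary,unknown,hind
DPpha 50,caribou,mountain,sedentary,unknown,hind
DPpha 51,caribou,tundra,planarly,male,hind
DPpha 52,caribou,tundra,planarly,female,hind
DPpha 53,caribou,tundra,planarly,female,hind
DPpha 54,caribou,tundra,planarly,unknown,hind
DPpha 55,caribou,tundra,planarly,unknown,hind
DPpha 56,caribou,tundra,planarly,unknown,hind
DPpha 57,caribou,tundra,planarly,unknown,hind
DPpha 58,caribou,tundra,planarly,unknown,hind
DPpha 59,caribou,tundra,planarly,unknown,hind
DPpha 60,caribou,tundra,planarly,unknown,hind
DPpha 61,caribou,boreal_forest,sedentary,female,hind
DPpha 62,caribou,boreal_forest,sedentary,unknown,hind
DPpha 63,caribou,boreal_forest,sedentary,unknown,hind
DPpha 64,caribou,boreal_forest,sedentary,unknown,hind
DPpha 65,caribou,boreal_forest,sedentary,unknown,hind
DPpha 66,caribou,boreal_forest,sedentary,unknown,hind
DPpha 67,caribou,boreal_forest,sedentary,unknown,hind
DPpha 68,caribou,boreal_forest,sedentary,unknown,hind
DPpha 69,caribou,boreal_forest,sedentary,unknown,hind
DPpha 70,caribou,boreal_forest,sedentary,unknown,hind
DPpha 71,granti,tundra,planarly,male,hind
DPpha 72,granti,tundra,planarly,male,hind
DPpha 73,groenlandicus,tundra,planarly,male,hind
DPpha 74,groenlandicus,tundra,planarly,male,hind
DPpha 75,pearyi,tundra,planarly,male,hind
DPpha 76,pearyi,tundra,planarly,male,hind
DPpha 77,pearyi,tundra,planarly,male,hind
DPpha 78,pearyi,tundra,planarly,male,hind
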