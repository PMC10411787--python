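specimen_id,subspecies,habitat,mobility,sex,limb
DPpha 1,caribou,mountain,altitudinal,male,fore
DPpha 2,caribou,mountain,altitudinal,male,fore
DPpha 3,caribou,mountain,altitudinal,male,fore
DPpha 4,caribou,mountain,altitudinal,female,fore
DPpha 5,caribou,mountain,altitudinal,unknown,fore
DPpha 6,caribou,mountain,altitudinal,unknown,fore
DPpha 7,caribou,mountain,sedentary,male,fore
DPpha 8,caribou,mountain,sedentary,female,fore
DPpha 9,caribou,mountain,sedentary,unknown,fore
DPpha 10,caribou,mountain,sedentary,unknown,fore
DPpha 11,caribou,mountain,sedentary,unknown,fore
DPpha 12,caribou,tundra,planarly,female,fore
DPpha 13,caribou,tundra,planarly,unknown,fore
DPpha 14,caribou,tundra,planarly,unknown,fore
DPpha 15,caribou,tundra,planarly,unknown,fore
DPpha 16,caribou,tundra,planarly,unknown,fore
DPpha 17,caribou,tundra,planarly,unknown,fore
DPpha 18,caribou,boreal_forest,sedentary,unknown,fore
DPpha 19,caribou,boreal_forest,sedentary,unknown,fore
DPpha 20,caribou,boreal_forest,sedentary,unknown,fore
DPpha 21,caribou,boreal_forest,sedentary,unknown,fore
DPpha 22,caribou,boreal_forest,sedentary,unknown,fore
DPpha 23,caribou,boreal_forest,sedentary,unknown,fore
DPpha 24,caribou,boreal_forest,sedentary,unknown,fore
DPpha 25,granti,tundra,planarly,male,fore
DPpha 26,granti,tundra,planarly,male,fore
DPpha 27,granti,tundra,planarly,male,fore
DPpha 28,granti,tundra,planarly,male,fore
DPpha 29,groenlandicus,tundra,planarly,unknown,fore
DPpha 30,groenlandicus,tundra,planarly,unknown,fore
DPpha 31,pearyi,tundra,planarly,male,fore
DPpha 32,pearyi,tundra,planarly,male,fore
DPpha 33,pearyi,tundra,planarly,male,fore
DPpha 34,pearyi,tundra,planarly,unknown,fore
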