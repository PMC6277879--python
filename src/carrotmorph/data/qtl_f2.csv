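qtl_name,measurement,trait,chromosome,closest_marker,lod,left_marker,right_marker,n_individuals
ht-2.1,manual,shoot_height,2,S2_43085743,32.49,S2_42846844,S2_43581817,316
ht-5.1,manual,shoot_height,5,S5_41414532,3.33,S5_6457993,S5_41951182,316
ht-7.1,manual,shoot_height,7,S7_28224489,10.84,S7_15056433,S7_29551603,316
sb-2.1,manual,shoot_biomass,2,S2_43085743,16.42,S2_42846844,S2_43581949,316
sb-3.1,manual,shoot_biomass,3,S3_38999634,4.16,S3_23294327,S3_48725969,316
sb-4.1,manual,shoot_biomass,4,S4_5516472,3.88,S4_2983852,S4_17556866,316
sb-7.1,manual,shoot_biomass,7,S7_29473453,11.12,S7_20379319,S7_34717088,316
ln-2.1,manual,petiole_number,2,S2_43085743,6.57,S2_42024242,S2_43581949,316
ht-2.2,image,shoot_height,2,S2_43085743,28.67,S2_42846844,S2_43581998,316
ht-7.2,image,shoot_height,7,S7_20387007,8.43,S7_11718785,S7_31550284,316
sa-2.1,image,shoot_area,2,S2_43085743,10.73,S2_42846844,S2_43581949,316
sa-3.1,image,shoot_area,3,S3_38999634,3.02,S3_23294327,S3_48725969,316
sa-7.1,image,shoot_area,7,S7_31972865,5.28,S7_19018242,S7_34717088,316
ln-2.2,image,petiole_number,2,S2_43581949,5.81,S2_42342776,S2_43581949,316
pw-1.1,image,petiole_width,1,S1_33448879,6.69,S1_29083233,S1_49929471,316
pw-2.1,image,petiole_width,2,S2_43085743,2.90,S2_42342776,S2_43581949,316
pw-4.1,image,petiole_width,4,S4_5516472,3.76,S4_2983852,S4_17556866,316
pw-7.1,image,petiole_width,7,S7_33430504,8.94,S7_20379319,S7_34717088,316
pw-8.1,image,petiole_width,8,S8_2442141,4.05,S8_1370824,S8_5678858,316
pl-2.1,image,petiole_length,2,S2_43085743,18.16,S2_42846844,S2_43581949,316
pl-3.1,image,petiole_length,3,S3_23294327,2.15,S3_23294327,S3_49446360,316
pl-7.1,image,petiole_length,7,S7_28187058,7.25,S7_20387007,S7_31550284,316
spc2-2.1,image,shoot_pc2,2,S2_43085743,21.10,S2_42846844,S2_43581949,316
spc2-3.1,image,shoot_pc2,3,S3_48507169,3.27,S3_23294327,S3_50144206,316
rl-1.1,manual,root_length,1,S1_38352734,6.47,S1_25151874,S1_49277871,316
rl-3.1,manual,root_length,3,S3_37060244,4.39,S3_23294327,S3_43735481,316
rl-7.1,manual,root_length,7,S7_833073,3.15,S7_442640,S7_3313327,316
rb-2.1,manual,root_biomass,2,S2_43085743,4.42,S2_42024242,S2_43581949,316
rb-7.1,manual,root_biomass,7,S7_28224489,3.99,S7_11718785,S7_34717122,316
rl-1.2,image,root_length,1,S1_38352734,10.44,S1_33448879,S1_47240093,316
rl-2.1,image,root_length,2,S2_43085743,7.21,S2_42024242,S2_43581949,316
rl-3.2,image,root_length,3,S3_23294327,5.23,S3_23294327,S3_36496196,316
rl-4.1,image,root_length,4,S4_5516472,7.43,S4_2983852,S4_8969556,316
ra-2.1,image,root_area,2,S2_43085743,3.80,S2_42024242,S2_43581949,316
ra-4.1,image,root_area,4,S4_5516472,2.84,S4_2983852,S4_8969556,316
rpc2-2.1,image,root_pc2,2,S2_43085743,21.10,S2_42846844,S2_43581949,316
rpc2-3.1,image,root_pc2,3,S3_48507169,3.27,S3_23294327,S3_50144206,316
rpc2-7.1,image,root_pc2,7,S7_28187058,8.78,S7_19018242,S7_32082761,316
rpc3-7.1,image,root_pc3,7,S7_15056433,2.80,S7_442640,S7_35971570,316
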