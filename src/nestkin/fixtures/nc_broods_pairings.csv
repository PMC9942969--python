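nest_id,maternal_lineage,maternal_species,hen_sampled,paternal_lineages,parasitic_clutch,host_nest,note
nest 7,AH1,ABDU,True,#9:2:ABDU,False,,
nest 10.1,AH2,ABDU,True,#10:1:ABDU;#11:3:ABDUxWMAxGFM,False,,AH63 sired by inferred father #10; lineage #10 shared with the parasitic clutch 10.2
nest 2,AH3,ABDU,True,#12:2:ABDUxWMA,False,,
nest 14/20,AH4,ABDU,True,#7:5:ABDU;#8:1:WMA,False,,AH48 sired by inferred father #8 (printed as wild mallard in the table but described as game-farm mallard in the narrative); lineage #7 shared with nest 11 where its species is listed as wild mallard
nest 15,AH5,ABDU,True,#13:3:ABDU,False,,
nest 16,AH7,ABDU,True,#14:5:ABDU,False,,
nest 12,AH8,ABDU,True,#2:5:ABDU;#3:1:ABDU,False,,AH126 has inferred father #3
nest 17,AH9,ABDU,True,#15:2:ABDU,False,,lineage #15 shared with nest 4
nest 18,AH10,ABDU,True,#1:5:ABDU;#21:1:ABDU,False,,AH168 sired by inferred father listed as #22 in the species note; lineage column value #21 kept
nest 3,AH11,ABDU,True,#19:2:ABDU;#20:1:ABDU,False,,AH154 sired by inferred father listed as #21 in the note; lineage column values #19/#20 kept
nest 4,AH13,ABDUxWMA,True,#15:4:ABDU,False,,lineage #15 shared with nest 17
nest 5,AH14,ABDUxWMA,True,#22:7:ABDU,False,,
nest 6,AH15,ABDU,True,#6:2:ABDU,False,,
nest 9,AH17,ABDUxWMAxGFM,True,#23:3:ABDUxWMA,False,,
nest 8,AH18,ABDU,True,#24:3:ABDU,False,,
nest 11,AH210,ABDU,True,#7:5:WMA,False,,lineage #7 shared with nest 14/20 where its species is listed as black duck
nest 19,AH16,ABDU,True,#4:4:ABDU;#16:1:GFM,False,,maternity assigned below 0.5 probability; mtDNA screen flagged this nest as parasitized while the nuclear pairing reads as extra-pair copulation
nest 1,AH12,ABDU,True,#5:3:ABDU,False,,maternity assigned below 0.5 probability; species column lists #4 but lineage column value #5 kept
nest 10.2,UNSAMPLED_F3,ABDU,False,#10:2:ABDU,True,nest 10.1,clutch dumped into nest 10 by an unsampled female; father shared with resident lineage #10
nest 13,AH19,ABDU,True,#17:6:ABDU;#18:1:ABDUxWMA,False,,maternity assigned below 0.5 probability; AH139 inferred father #18
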