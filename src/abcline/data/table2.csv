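# Reference dataset: five surgically treated basilar apex (BX) aneurysm
# patients from the published surgical series this analysis reproduces.
# Heights are signed mm above the dorsum sellae; width is lateral mm from
# the midline; cz/cl are the distances (mm) from the projected cranial
# point C to the zygomatic arch and to the lateral canthus.
#
# Transcription notes: the available text of the source table runs the
# numeric cells of each row together without delimiters. Cells were split
# using the accompanying results narrative as arbiter:
#   - height of A spans 3-12 mm across the five patients;
#   - patient 3 (failed pterional clipping, coating only) has C-Z 36 mm
#     and C-L 31 mm ("3.6 and 3.1 cm");
#   - the two orbitozygomatic (OZA) patients (4, 5) have both distances
#     below 30 mm; patient 5 matches the representative case report
#     (point C 2.3 cm above the zygomatic arch, 2.9 cm from the lateral
#     canthus);
#   - the two successfully clipped pterional patients (1, 2) have both
#     distances above 40 mm; patients operated without the OZA had
#     height of B above 6 mm.
#   - confidence: patient 1's cz/cl split (87, 85.1) is the least
#     constrained by the narrative (only "more than 4 cm" and the figure
#     caption's "more than 5 cm" apply) and should be treated as the
#     lowest-confidence cells in this table.
patient,age,sex,location,size_mm,ruptured,height_A_mm,height_B_mm,width_B_mm,cz_mm,cl_mm,approach
1,58,M,basilar_tip,7,ruptured,3,6,16.8,87,85.1,clipping via right pterional
2,77,F,BA-SCA,5,ruptured,6,9,13.9,57,47.9,clipping via left pterional with anterior clinoidectomy
3,74,F,BA-SCA,5,unruptured,9,12,9,36,31,coating via left pterional
4,79,F,basilar_tip,3,ruptured,12,6,16.8,15,29.5,clipping via right OZA
5,36,F,BA-SCA,7,unruptured,4,2.8,18,23.3,28.7,clipping via right OZA
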