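sick,control,one_stone,fat,food,bmi_class,category
0,0,0,1,1,underweight,RD
0,0,0,1,1,normal,OED
0,0,0,1,1,overweight,HD
0,0,0,1,1,obese,HD
0,0,1,0,1,underweight,RD
0,0,1,0,1,normal,OED
0,0,1,0,1,overweight,OED
0,0,1,0,1,obese,OED
0,0,1,1,0,underweight,RD
0,0,1,1,0,normal,RD
0,0,1,1,0,overweight,OED
0,0,1,1,0,obese,OED
0,0,1,1,1,underweight,RD
0,0,1,1,1,normal,RD
0,0,1,1,1,overweight,OED
0,0,1,1,1,obese,OED
0,1,0,0,1,underweight,RD
0,1,0,0,1,normal,HD
0,1,0,0,1,overweight,HD
0,1,0,0,1,obese,HD
0,1,0,1,0,underweight,RD
0,1,0,1,0,normal,BD
0,1,0,1,0,overweight,HD
0,1,0,1,0,obese,HD
0,1,0,1,1,underweight,RD
0,1,0,1,1,normal,BD
0,1,0,1,1,overweight,HD
0,1,0,1,1,obese,HD
0,1,1,0,0,underweight,RD
0,1,1,0,0,normal,BD
0,1,1,0,0,overweight,OED
0,1,1,0,0,obese,OED
0,1,1,0,1,underweight,RD
0,1,1,0,1,normal,BD
0,1,1,0,1,overweight,HD
0,1,1,0,1,obese,HD
0,1,1,1,0,underweight,RD
0,1,1,1,0,normal,RD
0,1,1,1,0,overweight,OED
0,1,1,1,0,obese,OED
0,1,1,1,1,underweight,RD
0,1,1,1,1,normal,BD
0,1,1,1,1,overweight,HD
0,1,1,1,1,obese,HD
1,0,0,0,1,underweight,RD
1,0,0,0,1,normal,BD
1,0,0,0,1,overweight,BD
1,0,0,0,1,obese,BD
1,0,0,1,0,underweight,RD
1,0,0,1,0,normal,BD
1,0,0,1,0,overweight,OED
1,0,0,1,0,obese,OED
1,0,0,1,1,underweight,RD
1,0,0,1,1,normal,BD
1,0,0,1,1,overweight,OED
1,0,0,1,1,obese,OED
1,0,1,0,0,underweight,RD
1,0,1,0,0,normal,BD
1,0,1,0,0,overweight,OED
1,0,1,0,0,obese,OED
1,0,1,0,1,underweight,RD
1,0,1,0,1,normal,BD
1,0,1,0,1,overweight,OED
1,0,1,0,1,obese,OED
1,0,1,1,0,underweight,RD
1,0,1,1,0,normal,OED
1,0,1,1,0,overweight,OED
1,0,1,1,0,obese,OED
1,0,1,1,1,underweight,RD
1,0,1,1,1,normal,OED
1,0,1,1,1,overweight,OED
1,0,1,1,1,obese,OED
1,1,0,0,0,underweight,RD
1,1,0,0,0,normal,BD
1,1,0,0,0,overweight,BD
1,1,0,0,0,obese,BD
1,1,0,0,1,underweight,RD
1,1,0,0,1,normal,BD
1,1,0,0,1,overweight,HD
1,1,0,0,1,obese,HD
1,1,0,1,0,underweight,RD
1,1,0,1,0,normal,BD
1,1,0,1,0,overweight,BD
1,1,0,1,0,obese,BD
1,1,0,1,1,underweight,RD
1,1,0,1,1,normal,BD
1,1,0,1,1,overweight,BD
1,1,0,1,1,obese,BD
1,1,1,0,0,underweight,RD
1,1,1,0,0,normal,BD
1,1,1,0,0,overweight,BD
1,1,1,0,0,obese,BD
1,1,1,0,1,underweight,RD
1,1,1,0,1,normal,BD
1,1,1,0,1,overweight,BD
1,1,1,0,1,obese,BD
1,1,1,1,0,underweight,RD
1,1,1,1,0,normal,BD
1,1,1,1,0,overweight,BD
1,1,1,1,0,obese,BD
1,1,1,1,1,underweight,RD
1,1,1,1,1,normal,BD
1,1,1,1,1,overweight,BD
1,1,1,1,1,obese,BD
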