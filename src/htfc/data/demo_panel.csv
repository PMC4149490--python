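plate,well,antigen,fluorochrome,clone
P1,A1,CD90,PE,5E10
P1,A2,CD31,PE,WM59
P1,A3,CD45,PE,HI30
P1,A4,CD9,PE,HI9a
P1,A5,CD10,PE,HI10a
P1,A6,CD44,PE,BJ18
P1,A7,CD73,PE,AD2
P1,A8,CD105,PE,43A3
P1,B1,CD3,FITC,UCHT1
P1,B2,CD24,FITC,ML5
P1,B3,CD29,FITC,TS2/16
P1,B4,CD34,FITC,581
P1,B5,CD49f,FITC,GoH3
P1,B6,CD54,FITC,HA58
P1,B7,CD326,FITC,9C4
P1,B8,CD166,FITC,3A6
P1,C1,CD4,APC,OKT4
P1,C2,CD8,APC,SK1
P1,C3,CD11b,APC,ICRF44
P1,C4,CD141,APC,M80
P1,C5,CD144,APC,BV9
P1,C6,CD146,APC,P1H12
P1,C7,CD47,APC,CC2C6
P1,C8,CD59,APC,p282
P1,H9,CONTROL,PE,
P1,H10,CONTROL,FITC,
P1,H11,CONTROL,APC,
P1,H12,CONTROL,PE,
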