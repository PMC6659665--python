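# Genome organization of the six newly sequenced Dendrolimus mitogenomes
# (D. kikuchii SM12/SM22, D. houi YN05/YN11, D. superans LY04/LY08).
# Coordinates are 1-based inclusive on the majority strand.
gene	strand	SM12	SM22	YN05	YN11	LY04	LY08
trnM	F	1-67	1-67	1-67	1-67	1-68	1-67
trnI	F	71-134	71-134	69-132	69-132	72-135	72-135
trnQ	R	132-200	132-200	130-198	130-198	133-201	133-201
nad2	F	257-1264	255-1262	254-1264	254-1264	256-1266	256-1266
trnW	F	1264-1334	1262-1332	1263-1332	1263-1332	1265-1336	1265-1335
trnC	R	1327-1392	1325-1390	1325-1391	1325-1391	1329-1394	1328-1393
trnY	R	1393-1460	1391-1458	1393-1463	1393-1463	1395-1460	1394-1459
cox1	F	1501-3031	1500-3030	1492-3022	1492-3022	1493-3023	1492-3022
trnL(UUR)	F	3032-3098	3031-3097	3023-3089	3023-3089	3024-3090	3023-3089
cox2	F	3099-3780	3098-3779	3090-3773	3090-3773	3091-3772	3090-3771
trnK	F	3781-3851	3780-3850	3775-3845	3775-3845	3773-3843	3772-3842
trnD	F	3852-3919	3851-3918	3847-3913	3847-3913	3847-3914	3846-3913
atp8	F	3920-4081	3919-4080	3914-4075	3914-4075	3915-4076	3914-4075
atp6	F	4075-4752	4074-4751	4069-4746	4069-4746	4070-4747	4069-4746
cox3	F	4759-5547	4760-5548	4762-5550	4762-5550	4760-5548	4759-5547
trnG	F	5550-5616	5551-5617	5553-5618	5553-5618	5551-5616	5550-5615
nad3	F	5617-5970	5618-5971	5619-5970	5619-5970	5617-5970	5616-5969
trnA	F	5973-6039	5974-6039	5971-6038	5971-6038	5975-6041	5974-6040
trnR	F	6058-6123	6058-6123	6048-6112	6048-6112	6055-6118	6054-6117
trnN	F	6145-6211	6145-6211	6118-6184	6118-6184	6120-6185	6119-6184
trnS(AGN)	F	6226-6293	6219-6286	6210-6277	6210-6277	6202-6269	6201-6268
trnE	F	6293-6357	6286-6350	6277-6345	6277-6345	6269-6333	6268-6333
trnF	R	6371-6437	6364-6430	6354-6420	6354-6420	6346-6412	6346-6412
nad5	R	6442-8181	6435-8174	6425-8167	6425-8167	6416-8158	6416-8158
trnH	R	8182-8246	8175-8239	8168-8231	8168-8231	8159-8226	8159-8226
nad4	R	8247-9585	8240-9578	8232-9570	8232-9570	8227-9565	8227-9565
nad4l	R	9620-9913	9611-9904	9602-9895	9602-9895	9604-9897	9604-9897
trnT	F	9918-9982	9909-9973	9900-9964	9900-9964	9905-9970	9905-9969
trnP	R	9983-10047	9974-10038	9965-10029	9965-10029	9971-10035	9970-10034
nad6	F	10056-10586	10047-10577	10038-10568	10038-10568	10044-10574	10043-10573
cob	F	10590-11738	10581-11729	10574-11722	10574-11722	10579-11727	10578-11726
trnS(UCN)	F	11737-11802	11728-11793	11726-11791	11726-11791	11731-11797	11730-11796
nad1	R	11802-12755	11793-12746	11791-12744	11791-12744	11797-12750	11796-12749
trnL(CUN)	R	12757-12827	12748-12818	12746-12813	12746-12813	12752-12820	12751-12819
rrnL	R	12828-14210	12819-14204	12814-14220	12814-14220	12821-14253	12820-14253
trnV	R	14211-14275	14205-14268	14221-14286	14221-14286	14254-14319	14254-14319
rrnS	R	14276-15058	14269-15051	14287-15062	14287-15063	14320-15101	14320-15100
AT region	F	15059-15377	15052-15370	15063-15381	15064-15382	15102-15417	15101-15417
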