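Accession	Submitted name	Proposed name	Species	Classification
T1EJE5	Uncharacterized protein	Pax	Helobdella_robusta	Annelida_Clitellata
T1G7D6	Uncharacterized protein	Pax1/9(f)	Helobdella_robusta	Annelida_Clitellata
T1EIE6	Uncharacterized protein	Pax2/5/8?(f)	Helobdella_robusta	Annelida_Clitellata
T1EH18	Uncharacterized protein	Pax2/5/8(f)	Helobdella_robusta	Annelida_Clitellata
T1FMW8	Uncharacterized protein	Pax3/7A	Helobdella_robusta	Annelida_Clitellata
T1G8F8	Uncharacterized protein	Pax3/7B(f)	Helobdella_robusta	Annelida_Clitellata
T1F6U6	Uncharacterized protein	Pax6A	Helobdella_robusta	Annelida_Clitellata
T1G400	Uncharacterized protein	Pax6B(f)	Helobdella_robusta	Annelida_Clitellata
T1EHA5	Uncharacterized protein	Paxβ1(f)	Helobdella_robusta	Annelida_Clitellata
T1G182	Uncharacterized protein	Paxβ2(f)	Helobdella_robusta	Annelida_Clitellata
R7VKC0	Uncharacterized protein	Pax1/9(f)	Capitella_teleta	Annelida_Polychaeta
R7T7W6	Uncharacterized protein	Pax2/5/8(f)	Capitella_teleta	Annelida_Polychaeta
R7TKD0	Uncharacterized protein	Pax3/7(f)	Capitella_teleta	Annelida_Polychaeta
R7TWR1	Uncharacterized protein	Paxβ(f)	Capitella_teleta	Annelida_Polychaeta
R7UF83	Uncharacterized protein	PoxN	Capitella_teleta	Annelida_Polychaeta
K1QWY6	Paired box protein Pax-6	eyg	Crassostrea_gigas	Mollusca_Bivalvia
K1QYI7	Paired box protein Pax-2-A	Pax2/5/8	Crassostrea_gigas	Mollusca_Bivalvia
K1R3J2	Paired box protein Pax-2-A	Paxβ	Crassostrea_gigas	Mollusca_Bivalvia
K1S548	Paired box protein Pax-6	Paxβ(?)	Crassostrea_gigas	Mollusca_Bivalvia
K1R993	Paired box protein Pax-8	PoxN	Crassostrea_gigas	Mollusca_Bivalvia
Unigene67849_All_[769..2]	Unigene67849_All_[769..2]	Pax1/9(f)	Mytilus_galloprovincialis	Mollusca_Bivalvia
CL6200.Contig1_All_[141..1748]	CL6200.Contig1_All_[141..1748]	Pax2/5/8	Mytilus_galloprovincialis	Mollusca_Bivalvia
CL6200.Contig2_All_[141..1640]	CL6200.Contig2_All_[141..1640]	Pax2/5/8	Mytilus_galloprovincialis	Mollusca_Bivalvia
CL6200.Contig3_All_[308..1978]	CL6200.Contig3_All_[308..1978]	Pax2/5/8	Mytilus_galloprovincialis	Mollusca_Bivalvia
CL6200.Contig4_All_[308..2086]	CL6200.Contig4_All_[308..2086]	Pax2/5/8	Mytilus_galloprovincialis	Mollusca_Bivalvia
CL6200.Contig5_All_[308..1885]	CL6200.Contig5_All_[308..1885]	Pax2/5/8	Mytilus_galloprovincialis	Mollusca_Bivalvia
CL6200.Contig6_All_[308..1993]	CL6200.Contig6_All_[308..1993]	Pax2/5/8	Mytilus_galloprovincialis	Mollusca_Bivalvia
Unigene61312_All_[208..2]	Unigene61312_All_[208..2]	Pax3/7(f)	Mytilus_galloprovincialis	Mollusca_Bivalvia
CL16191.Contig1_All_[203..730]	CL16191.Contig1_All_[203..730]	Pax6	Mytilus_galloprovincialis	Mollusca_Bivalvia
Unigene25062_All_[203..1645]	Unigene25062_All_[203..1645]	Pax6	Mytilus_galloprovincialis	Mollusca_Bivalvia
CL16191.Contig2_All_[1..435]	CL16191.Contig2_All_[1..435]	Pax6(f)	Mytilus_galloprovincialis	Mollusca_Bivalvia
Unigene43617_All_[929..24]	Unigene43617_All_[929..24]	PoxN	Mytilus_galloprovincialis	Mollusca_Bivalvia
Scaffold15272:139788-157863	Ocbimv22007526m.p	Pax2/5/8	Octopus_bimaculoides	Mollusca_Cephalopoda
Scaffold183397:4017-6471	Ocbimv22011111m.p	Pax6	Octopus_bimaculoides	Mollusca_Cephalopoda
Scaffold17697:31829-33450	Ocbimv22010462m.p	Pax9	Octopus_bimaculoides	Mollusca_Cephalopoda
Scaffold10474:604998-663118	Ocbimv22000807m.p	Paxβ	Octopus_bimaculoides	Mollusca_Cephalopoda
Scaffold15584:42867-65908	Ocbimv22007901m.p	PoxN	Octopus_bimaculoides	Mollusca_Cephalopoda
gi|524867779|ref|XP_005090697.1	PREDICTED: mucin-5AC	Paxβ	Aplysia_californica	Mollusca_Gastropoda
A0A0B6YZY1	Uncharacterized protein (Fragment) GN = ORF42948	Pax2/5/8?(f)	Arion_vulgaris	Mollusca_Gastropoda
A0A0B7A551	Uncharacterized protein (Fragment) GN = ORF96941	Pax3/7(f)	Arion_vulgaris	Mollusca_Gastropoda
A0A0B7A6X2	Uncharacterized protein (Fragment) GN = ORF96938	Pax3/7(f)	Arion_vulgaris	Mollusca_Gastropoda
A0A0B7A6Y7	Uncharacterized protein (Fragment) GN = ORF96935	Pax3/7(f)	Arion_vulgaris	Mollusca_Gastropoda
A0A0B6Y326	Uncharacterized protein (Fragment) GN = ORF11503	Pax6(f)	Arion_vulgaris	Mollusca_Gastropoda
A0A0B6YFJ8	Uncharacterized protein (Fragment) GN = ORF24120	Pax6(f)	Arion_vulgaris	Mollusca_Gastropoda
A0A0B7A5F8	Uncharacterized protein	PoxN	Arion_vulgaris	Mollusca_Gastropoda
gi|908452192|ref|XP_013082659.1	PREDICTED: mucin-5AC-like	Paxβlike	Biomphalaria_glabrata	Mollusca_Gastropoda
A0A0B6VJL1	Paired box 6 protein	eyg	Lottia_gigantea	Mollusca_Gastropoda
V4A9T6	Uncharacterized protein	Pax1/9	Lottia_gigantea	Mollusca_Gastropoda
V3ZI38	Uncharacterized protein	Pax2/5/8(f)	Lottia_gigantea	Mollusca_Gastropoda
V4AMZ8	Uncharacterized protein	Pax3/7(f)	Lottia_gigantea	Mollusca_Gastropoda
V3ZQV3	Uncharacterized protein	Pax6(f)	Lottia_gigantea	Mollusca_Gastropoda
Contig4275(2463977-2470937)	LgGsHFWreduced.5213	Paxβ	Lottia_gigantea	Mollusca_Gastropoda
V4B0D1	Uncharacterized protein	Paxβ(f)	Lottia_gigantea	Mollusca_Gastropoda
V3ZWA2	Uncharacterized protein	PoxN(f)	Lottia_gigantea	Mollusca_Gastropoda
Q25411	Pax6-like protein	Pax6	Lineus_sanguineus	Nemertea_Anopla
O96756	DtPax-6 protein	Pax6B	Girardia_tigrina	Platyhelminthes_Rhabditophora
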