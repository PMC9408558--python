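# ABC Pfam profile catalog: accession, name, clan, category, class_hint
# category: NBD (nucleotide-binding domain), TMD (transmembrane domain), other
# class_hint names the TMD structural class suggested by the profile, where known.
# The list is editable: rows follow the published family->structural-class map
# (five clans with ABC hits); accessions are the current Pfam ones for the
# named families.  Lookups also fall back to the profile *name*, so local or
# synthetic profiles can be added by name alone.
PF00005	ABC_tran	CL0023	NBD
PF00664	ABC_membrane	CL0241	TMD	Pgp-like
PF06472	ABC_membrane_2	CL0241	TMD	Pgp-like
PF12848	ABC_membrane_3	CL0241	TMD	Pgp-like
PF05992	SbmA_BacA	CL0241	TMD	Pgp-like
PF01061	ABC2_membrane	CL0181	TMD	ABCG2-like
PF12679	ABC2_membrane_2	CL0181	TMD	ABCG2-like
PF12698	ABC2_membrane_3	CL0181	TMD	ABCG2-like
PF12730	ABC2_membrane_4	CL0181	TMD	ABCG2-like
PF13346	ABC2_membrane_5	CL0181	TMD	ABCG2-like
PF12910	ABC2_membrane_6	CL0181	TMD	ABCG2-like
PF13748	ABC2_membrane_7	CL0181	other
PF06422	PDR_CDR	CL0181	other
PF03379	CcmB	CL0181	TMD	ABCG2-like
PF12051	DUF3533	CL0181	TMD	ABCG2-like
PF02588	YitT_membrane	CL0181	other
PF00528	BPD_transp_1	CL0404	TMD	MalFG-like
PF02687	FtsX	CL0404	TMD	MacB-like
PF12704	MacB_PCD	CL0404	TMD	MacB-like
PF05232	DUF717	CL0404	TMD	Bce-like
PF09822	DUF1430	CL0404	other
PF04239	LptF_LptG	CL0404	TMD	LptFG-like
PF04290	Gx_transp	CL0606	TMD	EcfT-like
PF12822	ECF_trnsprt	CL0606	TMD	EcfT-like
PF02361	CbiQ	-	TMD	EcfT-like
PF01032	FecCD	CL0142	TMD	BtuCD-like
PF00950	ABC-3	CL0142	TMD	BtuCD-like
PF02405	MlaE	CL0142	TMD	MlaE-like
PF01458	SUF	CL0142	TMD	BtuCD-like
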