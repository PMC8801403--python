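##gff-version 3
chr1	test	gene	101	1900	.	+	.	ID=G1;gene_id=G1
chr1	test	transcript	101	1900	.	+	.	ID=T1;Parent=G1;gene_id=G1;transcript_id=T1;transcript_type=protein_coding
chr1	test	exon	101	800	.	+	.	Parent=T1;gene_id=G1;transcript_id=T1;transcript_type=protein_coding
chr1	test	exon	901	1700	.	+	.	Parent=T1;gene_id=G1;transcript_id=T1;transcript_type=protein_coding
chr1	test	exon	1801	1900	.	+	.	Parent=T1;gene_id=G1;transcript_id=T1;transcript_type=protein_coding
chr1	test	CDS	651	800	.	+	0	Parent=T1;gene_id=G1;transcript_id=T1;transcript_type=protein_coding
chr1	test	CDS	901	1700	.	+	0	Parent=T1;gene_id=G1;transcript_id=T1;transcript_type=protein_coding
chr1	test	CDS	1801	1850	.	+	2	Parent=T1;gene_id=G1;transcript_id=T1;transcript_type=protein_coding
chr2	test	gene	2001	3500	.	-	.	ID=G2;gene_id=G2
chr2	test	transcript	2001	3500	.	-	.	ID=T2;Parent=G2;gene_id=G2;transcript_id=T2;transcript_type=protein_coding
chr2	test	exon	2001	2300	.	-	.	Parent=T2;gene_id=G2;transcript_id=T2;transcript_type=protein_coding
chr2	test	exon	2401	2700	.	-	.	Parent=T2;gene_id=G2;transcript_id=T2;transcript_type=protein_coding
chr2	test	exon	2801	3500	.	-	.	Parent=T2;gene_id=G2;transcript_id=T2;transcript_type=protein_coding
chr2	test	CDS	2401	2700	.	-	0	Parent=T2;gene_id=G2;transcript_id=T2;transcript_type=protein_coding
chr3	test	gene	5001	5400	.	+	.	ID=G3;gene_id=G3
chr3	test	transcript	5001	5400	.	+	.	ID=T3;Parent=G3;gene_id=G3;transcript_id=T3;transcript_type=lncRNA
chr3	test	exon	5001	5400	.	+	.	Parent=T3;gene_id=G3;transcript_id=T3;transcript_type=lncRNA
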