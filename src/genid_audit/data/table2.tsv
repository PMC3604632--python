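# Published multi-database position report for SNP rs2844871.
# One row per (database, version, build, location) mapping; status encodes
# "SNP is listed, but no position information given" and "NA" cells.
rsid	database	version	genome_build	ncbi_build	dbsnp_build	chromosome	position	status
rs2844871	Affymetrix 6.0	NetAffx 30	Hg18	NCBI36	Not specified	22	14459243	mapped
rs2844871	Affymetrix 6.0	NetAffx 31	Hg19	GRCH 37	131			listed_no_position
rs2844871	Affymetrix 6.0	NetAffx 32	Hg19	GRCH 37	132			listed_no_position
rs2844871	UCSC genome browser	July 2011	Hg18	NCBI36	128	22	14459242	mapped
rs2844871	UCSC genome browser	July 2011	Hg18	NCBI36	130	14	19763716	mapped
rs2844871	UCSC genome browser	July 2011	Hg18	NCBI36	130	22	16079242	mapped
rs2844871	UCSC genome browser	July 2011	Hg19	GRCH 37	132	14	19763467	mapped
rs2844871	UCSC genome browser	July 2011	Hg19	GRCH 37	132	22	16078993	mapped
rs2844871	UCSC genome browser	July 2011	Hg19	GRCH 37	132	Un_gl000244	34403	mapped
rs2844871	UCSC genome browser	July 2011	Hg19	GRCH 37	135	14	19763467	mapped
rs2844871	UCSC genome browser	July 2011	Hg19	GRCH 37	135	22	16078993	mapped
rs2844871	UCSC genome browser	July 2011	Hg19	GRCH 37	135	Un_gl000244	34403	mapped
rs2844871	dbSNP	July 2011	Hg19	NCBI 37.1	132	2	125655701	mapped
rs2844871	dbSNP	October 2012	Hg19	NCBI 37.3	137	14	19763717	mapped
rs2844871	dbSNP	October 2012	Hg19	NCBI 37.3	137	22	16079243	mapped
rs2844871	dbSNP	October 2012	Hg19	NCBI 37.3	137			not_available
rs2844871	dbSNP	October 2012	Hg19	NCBI 37.3	137	2	124523528	mapped
rs2844871	HapMap	Release 27	Hg18	Not specified	Not specified	22	14459243	mapped
rs2844871	HapMap	Release 28	Hg18	NCBI36	126	22	14459243	mapped
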