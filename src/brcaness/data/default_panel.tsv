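# Default BRCAness gene panel: 40 BRCAness genes plus the BRCA1/BRCA2 references.
# Genome build: GRCh38. TSS coordinates are approximate canonical-transcript
# transcription start sites (1-based); override via a custom panel table if a
# different annotation is required.
symbol	is_reference	tss_chrom	tss_pos
ATM	0	chr11	108222484
ATR	0	chr3	142562322
AURKA	0	chr20	56392337
BAP1	0	chr3	52413500
BARD1	0	chr2	214809709
BLM	0	chr15	90717327
BRCA1	1	chr17	43125483
BRCA2	1	chr13	32315474
BRIP1	0	chr17	61863558
CDK12	0	chr17	39461486
CHD4	0	chr12	6571547
CHEK1	0	chr11	125624882
CHEK2	0	chr22	28734305
EMSY	0	chr11	76444604
ERCC1	0	chr19	45449393
FANCA	0	chr16	89816647
FANCC	0	chr9	95317710
FANCD2	0	chr3	10026437
FANCE	0	chr6	35452337
FANCF	0	chr11	22625558
FANCI	0	chr15	89244869
KMT2A	0	chr11	118436492
MRE11A	0	chr11	94512000
MYC	0	chr8	127735434
NBS1	0	chr8	89984733
PALB2	0	chr16	23652631
PARP1	0	chr1	226408093
PAXIP1	0	chr7	154794341
PLK1	0	chr16	23677656
PTEN	0	chr10	87863113
RAD50	0	chr5	132556109
RAD51	0	chr15	40695174
RAD51B	0	chr14	67819779
RAD51C	0	chr17	58692602
RAD51D	0	chr17	35119580
RAD52	0	chr12	984085
SAMHD1	0	chr20	36951708
SEM1	0	chr7	96342097
TP53	0	chr17	7687550
TP53BP1	0	chr15	43511787
WEE1	0	chr11	9573580
WRN	0	chr8	31033790
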