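# Demo configuration: a small two-chromosome genome that runs the whole
# pipeline in seconds. Section names match the CLI subcommands.

[simulate]
n_genes = 40
n_te = 60
n_clusters = 40
chrom_length = 300000
n_dmrs_per_context = 12
n_pattern_loci = 10

[diffexpr]
fc_min = 2.0
p_max = 0.01
q_max = 0.01

[eld]
fc_min = 1.0
p_max = 0.05

[cistrans]
alpha = 0.05
min_fpkm = 2.0
min_allelic_reads = 20

[homoeolog]
tau = 4.0

[sirna]
max_gap = 100
min_reads = 10
min_span = 50
fc = 1.5
q_max = 0.05
flank = 2000

[methylome]
window = 100
min_reads = 10
q_max = 0.05
merge_gap = 200
mpv_q_max = 0.01
error_rate = 0.006
promoter = 2000

[integrate]
n_permutations = 200
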