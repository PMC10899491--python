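"""Simulate a bulk-segregant experiment and write its 4-sample VCF.

Builds the reference design (5 x 30 Mb chromosomes, 299 F3 plants, 10%
tails pooled) with one additive QTL at Chr3:15 Mb, then reports what the
generative model produced.
"""

import numpy as np

from bulkmap import simulate_experiment, study_design

genome, qtls, config = study_design(seed=7, heritability=0.48)
table, truth = simulate_experiment(genome, qtls, config, vcf_path="sim.vcf")

het_f3 = np.mean(truth.dosages == 1)
print(f"markers simulated        : {len(table)}")
print(f"pool sizes (low/high)    : {len(truth.low_ids)}/{len(truth.high_ids)}")
print(f"F3 heterozygosity at QTL : {het_f3:.3f}  (expected 1/4 after two selfings)")
print(f"phenotype SD             : {truth.phenotypes.std():.3f}")
print("wrote sim.vcf with samples P1, P2, LOW, HIGH (GT:AD:DP)")
# The pooled allele depths in LOW/HIGH carry the association signal the
# downstream ED and delta-SNP-index scans will look for.
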