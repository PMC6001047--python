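"""Build a 96-channel mutational profile and compute mutation burden.

Simulates one sample whose SNVs follow a mixture of two catalog signatures,
re-reads the emitted VCF, classifies every SNV into its trinucleotide
channel, and reports the mutation prevalence (mutations per megabase).
"""

import tempfile
from pathlib import Path

from pyfaidx import Fasta

from mutsig96 import (
    CHANNEL_LABELS,
    build_profile,
    check_against_reference,
    load_catalog,
    make_reference,
    packaged_catalog_path,
    prevalence,
    read_vcf,
    simulate_sample,
)

workdir = Path(tempfile.mkdtemp())
cat = load_catalog(packaged_catalog_path()).subset(["Signature_1", "Signature_2"])

ref_path = make_reference(workdir / "ref.fa", length=50_000, gc_bias=0.41, seed=7)
vcf_path, _ = simulate_sample(
    ref_path, cat, weights=[0.7, 0.3], n_mutations=450, seed=7,
    out_vcf=workdir / "sample.vcf",
)

records, report = read_vcf(vcf_path, "sample01")
reference = Fasta(str(ref_path))
accepted, rejected = check_against_reference(records, reference)
profile, skipped = build_profile(accepted, reference, "sample01")

print(f"parsed {report.n_parsed} rows, accepted {report.n_accepted} SNVs")
print(f"profile total: {profile.total} mutations over 96 channels")
top = profile.counts.argsort()[::-1][:3]
for k in top:
    print(f"  most mutated channel: {CHANNEL_LABELS[k]}  count={profile.counts[k]}")

# burden over a custom 30 Mb territory (exome-sized)
res = prevalence(profile.total, "custom", territory_mb=30, sample_id="sample01")
print(f"prevalence: {res.per_mb:.2f} mutations/Mb -> hypermutated={res.hypermutated}")
# a sample is hypermutated only strictly above 12 mutations per megabase
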