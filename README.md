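# chargescan

Proteome-wide screening for **charge clusters** in protein sequences:
runs of residues significantly enriched in positive (Lys, Arg) or
negative (Asp, Glu) charge. Such clusters mediate electrostatic
interactions — protein sorting, translocation, DNA binding, capsid
assembly — and short cationic ones are candidate cell-penetrating
peptides (CPPs). The package targets the kind of screen performed on
viral proteomes, where clusters are detected, mapped relative to Pfam
functional domains, grouped when conserved across proteins, and
compared between virus families and genome groups.

## The statistic

A window of width *w* (default 20) slides along each protein. Under
the null model, the count *k* of charged residues of one sign in a
window is Binomial(*w*, *p₀*), with *p₀* the background frequency of
that charge class (by default the proteome-wide pooled frequency).
A window is significant when its upper-tail probability

&nbsp;&nbsp;&nbsp;&nbsp;P(X ≥ k) = Σ<sub>j=k..w</sub> C(w, j) p₀ʲ (1−p₀)ʷ⁻ʲ ≤ α&nbsp;&nbsp;&nbsp;(default α = 10⁻⁵)

Residues covered by at least one significant window are unioned;
each maximal contiguous run, trimmed inward so it starts and ends on
a charged residue, is reported as one charge cluster (PCC or NCC by
sign). Because of trimming, clusters may be shorter than *w*.
Equivalently, a window triggers when *k* reaches the critical count
k\* = min{k : P(X ≥ k) ≤ α}; e.g. k\*(20, 0.05, 10⁻⁵) = 8.

Downstream, each cluster is assigned one location category relative
to merged domain intervals (N-terminal / domain / interdomain /
C-terminal), clusters recurring identically in ≥ 2 proteins form
conserved groups, positive clusters of 7–30 aa are flagged as CPP
candidates, and a chi-square test compares the location distribution
of PCCs vs NCCs.

## Worked example

Simulate a 50-protein proteome with a positive 15-mer planted into
three proteins and one negative 25-mer, scan it, and group conserved
clusters:

```python
from chargescan import (PlantSpec, Polarity, ScanConfig, SimConfig,
                        generate_proteome, scan_proteome, group_conserved,
                        chi_square_independence)

sim = SimConfig(
    n_proteins=50, seed=7,
    plant_specs=(PlantSpec(Polarity.POSITIVE, 15, copies=3),
                 PlantSpec(Polarity.NEGATIVE, 25)),
)
records, truths, domains, metadata = generate_proteome(sim)
clusters, labels = scan_proteome(records, ScanConfig())
for c in clusters:
    print(f"{c.protein_id} {c.polarity.value:8s} {c.start:>5}-{c.end:<5} "
          f"len={c.length:<3} net={c.net_charge:+d} p={c.min_window_p:.2e} "
          f"cpp={c.cpp_candidate}")
groups = group_conserved(clusters, identity_threshold=1.0)
for g in groups:
    print(f"group {g.group_id}: {g.polarity.value}, {g.n_proteins} proteins, "
          f"sequence {g.representative_sequence}")
```

prints

```
SYN0009 positive   157-171   len=15  net=+15 p=8.07e-12 cpp=True
SYN0012 positive   360-374   len=15  net=+15 p=8.07e-12 cpp=True
SYN0031 negative    26-50    len=25  net=-25 p=4.16e-19 cpp=False
SYN0038 positive    73-87    len=15  net=+15 p=8.07e-12 cpp=True
group 1: positive, 3 proteins, sequence RRKKKRRRRRRKRRK
```

All four planted clusters are recovered at their exact coordinates
(`min_window_p` is the smallest window tail probability inside each
cluster; the three 15-mers are CPP candidates because they are
positive and 7–30 aa long), and the three identical copies form one
conserved group. The classical contingency analysis of cluster
locations runs on any 2×4 count table:

```python
res = chi_square_independence([[97, 10, 14, 5], [85, 29, 34, 46]])
print(f"chi2 = {res.statistic:.2f}, df = {res.df}, p = {res.p_value:.1e}")
# chi2 = 38.64, df = 3, p = 2.1e-08
```

showing that positive clusters concentrate inside functional domains
while negative clusters favour C-terminal regions.

The same pipeline is available from the shell:

```bash
chargescan simulate --n-proteins 50 --seed 7 --out sim/
chargescan all --fasta sim/proteome.fasta --domains sim/domains.tsv \
    --metadata sim/meta.tsv --out run/
```

writing `clusters.tsv`, `proteins.tsv`, `groups.tsv`, `summary.tsv`
and a `run_manifest.json` into `run/`.

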