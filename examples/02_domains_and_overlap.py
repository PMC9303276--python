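"""Higher-order organisation: ini-domains, clusters and the overlap permutation test.

Builds a dense origin set, merges it into ini-domains (gap <= 100 kb, >= 6
members), clusters one efficiency class at 30 kb, summarises inter-origin
distances, and tests whether a set of intervals overlaps another more than
chance under per-chromosome random re-placement.
"""

import numpy as np

from iniseq2 import (
    GenomeLayout,
    Interval,
    build_ini_domains,
    cluster_origins,
    inter_origin_distances,
    intersect_with_tolerance,
    permutation_overlap_test,
    summarize_distances,
)
from iniseq2.caller import OriginCall

g = np.random.default_rng(0)
layout = GenomeLayout((("chr1", 5_000_000),))

# three tight groups of origins plus scattered singletons
starts = np.sort(np.concatenate([
    1_000_000 + np.arange(8) * 20_000,
    2_500_000 + np.arange(7) * 15_000,
    g.integers(0, 4_990_000, 10),
]))
origins = [
    OriginCall("chr1", int(s), int(s) + 800, 8.0, 2.0, 0.9,
               class_label="high" if k % 2 else "low")
    for k, s in enumerate(starts)
]

domains = build_ini_domains(origins, max_gap=100_000, min_origins=6)
print(f"{len(domains)} ini-domains (>= 6 origins within 100 kb):")
for d in domains:
    print(f"  {d.chrom}:{d.start}-{d.end}  members={d.n_origins} "
          f"(high={d.n_high}, low={d.n_low})")

high = [o for o in origins if o.class_label == "high"]
clusters = cluster_origins(high, cluster_dist=30_000)
print(f"{len(clusters)} clusters of high-class origins at 30 kb")

dist = summarize_distances(inter_origin_distances(origins))
print(f"inter-origin distance: median {dist['median']:.0f} bp "
      f"(IQR {dist['q1']:.0f}-{dist['q3']:.0f}, n={dist['n']})")

# overlap of the origin set with the domains it came from, versus chance
A = [Interval(o.chrom, o.start, o.end) for o in origins]
B = [d.interval for d in domains]
venn = intersect_with_tolerance(A, B, max_dist=0)
res = permutation_overlap_test(A, B, layout, max_dist=0, n_perm=10_000, seed=0)
print(f"observed A-in-B overlap: {venn.n_intersect}/{len(A)}; "
      f"permutation mean {res.permuted_mean:.1f} (sd {res.permuted_sd:.1f})")
print(f"Z = {res.z:.1f}, p = {res.p:g}  "
      f"(floor 1/n_perm = {1 / res.n_perm:g} when no permutation matches)")
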