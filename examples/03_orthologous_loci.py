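"""Call presence/absence of ERV loci at orthologous positions.

Ancestral insertions should be found in the second species; insertions
younger than the split should hit an empty pre-integration site whose
4-bp target-site duplication is recoverable - the signature that dates
an insertion relative to the speciation.
"""

from ervfossil import GenomeIndex, call_orthology
from ervfossil.simulate import InsertionEvent, SimConfig, simulate

events = tuple(
    [InsertionEvent(12e6, "infection", "ancestral")] * 4
    + [InsertionEvent(3e6, "retrotransposition", "A")] * 4)
cfg = SimConfig(seed=9, genome_len=300_000, split_time_years=10e6,
                insertion_events=events, solo_fraction=0.25)
res = simulate(cfg)

index = GenomeIndex(res.genome_b)
truth = res.truth.set_index("locus_id")
for locus in res.loci_a:
    lid = locus.locus_id.rsplit("_", 1)[0]
    call = call_orthology(locus, res.genome_a, index,
                          res.config.ltr_len, "B")
    row = truth.loc[lid]
    tsd = f" tsd={call.tsd_seq}" if call.tsd_seq else ""
    print(f"{lid} ({row.lineage:9s} {row.kind:8s}) -> {call.state}{tsd}")
# present_* states mark pre-split (orthologous) insertions; absent_empty
# with a 4-bp TSD marks insertions younger than the species split.
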