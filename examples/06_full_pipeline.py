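"""The whole funnel on a synthetic world with planted transfers.

Generates a compact world (6 genomes x 250 genes, ~2% planted transfers,
sequence content for genome_00), runs screening -> tree validation ->
contamination filtering -> characterization, and scores the calls against
the generator's truth ledger."""

import json
import tempfile
from pathlib import Path

from hgtscan import (
    PipelineConfig, WorldConfig, generate_world, run_pipeline, scorecard,
)

with tempfile.TemporaryDirectory() as tmp:
    world = Path(tmp) / "world"
    cfg = WorldConfig(seed=42, n_genomes=6, genes_per_genome=250,
                      sequence_genomes=("genome_00",))
    truth = generate_world(cfg, world)
    print(f"planted transfers: {(truth['gene_class'] == 'hgt').sum()}")

    report, art = run_pipeline(world, PipelineConfig(n_perm=199, seed=1))

    print("\nfunnel:", json.dumps(report.funnel, indent=1))
    sc = scorecard(truth, art["candidates"], art["confirmed"], art["final"])
    print(f"recall={sc['final']['sensitivity']:.3f} "
          f"FDR={sc['final']['fdr']:.3f}")
    print("events:", report.events)
    print("donor mix (%):", report.donor_percentages)
    print("Ka/Ks classes:", report.kaks_classes)
    print("intron gain %:", report.intron.get("gain_pct"))
    print("intron origins:", {k: report.intron[k] for k in
                              ("origin_found_pct", "origin_mean_identity")
                              if k in report.intron})
    print("expression intron-higher %:",
          report.expression.get("fraction_intron_higher_pct"))

print("\nThe funnel counts shrink monotonically; the scorecard verifies the")
print("calls against the planted truth (high recall, near-zero FDR).")
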