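"""Cluster a repertoire into clones and inspect the most expanded ones.

A clone = all variable-region sequences with an identical CDRH3 amino-acid
sequence.  y counts the reads behind a clone (clonal expansion), x the
distinct amino-acid variants within it (diversification); x <= y always.
"""

import tempfile
from pathlib import Path

from igkit import RunConfig, SimulationConfig, run_individual, simulate_dataset
from igkit.clonal import analyze_clone, top_k_clones

with tempfile.TemporaryDirectory() as td:
    cfg = SimulationConfig(seed=7, n_clones=15, n_reads=400, shm_rate=2.0, seq_error_rate=0.0)
    sim = simulate_dataset(cfg, Path(td) / "sim")
    rc = RunConfig(
        replicates=[tuple(map(str, p)) for p in sim["fastq"]],
        germline=str(sim["germline"]),
        outdir=Path(td) / "results",
    )
    result = run_individual(rc, 0)

    print("rank  y(reads)  x(unique AA)  similarity  CDRH3")
    for rank, clone in enumerate(top_k_clones(result.clones, k=5), start=1):
        analyze_clone(clone)
        print(f"{rank:4}  {clone.y:8}  {clone.x:12}  {clone.similarity:10.3f}  {clone.cdrh3_aa}")
    # 'similarity' scores the clone member closest to the column-vote
    # consensus of the clone's multiple sequence alignment.
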