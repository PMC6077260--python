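"""Export an MS-ready variable-region database.

Truncates every heavy-chain sequence at the FR4 anchor (VTVSS in human) and
appends the trypsin cleavage suffix ASTK, producing a protein FASTA suitable
for LC-MS/MS spectral interpretation of serum antibodies, plus the AA -> DNA
mapping that links each database entry back to its supporting reads.
"""

import tempfile
from pathlib import Path

from igkit import RunConfig, SimulationConfig, run_individual, simulate_dataset
from igkit.isotype import HUMAN_TABLE
from igkit.msdb import CleavageRule, append_cleavage_suffix

with tempfile.TemporaryDirectory() as td:
    cfg = SimulationConfig(seed=5, n_clones=8, n_reads=100, shm_rate=0.0, seq_error_rate=0.0)
    sim = simulate_dataset(cfg, Path(td) / "sim")
    rc = RunConfig(
        replicates=[tuple(map(str, p)) for p in sim["fastq"]],
        germline=str(sim["germline"]),
        outdir=Path(td) / "results",
    )
    result = run_individual(rc, 0)

    suffixed = append_cleavage_suffix(result.records, CleavageRule("human"), HUMAN_TABLE)
    for rec, aa in suffixed[:3]:
        print(f"{rec.isotype:5} ...{aa[-20:]}")
    print("\nevery sequence now ends with the cleavage suffix 'ASTK',")
    print("giving trypsin a K residue to cut at the variable-region C terminus")
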