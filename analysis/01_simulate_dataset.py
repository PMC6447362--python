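#!/usr/bin/env python
"""Generate the study's synthetic dataset and write it to scratch/dataset/.

Produces a 200-gene annotation, matched UPF1-like / Pol II-like / input
coverage tracks (Bedgraph) and exonic RNA reads (BED), all seeded, plus the
generating ground truth.  The raw tracks run to tens of MB, so they live
under scratch/ and are regenerated on demand; later scripts re-simulate
from the same seed instead of reading them back.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from metachip import SimulationSpec, simulate, write_dataset

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "dataset"


def main() -> None:
    spec = SimulationSpec(seed=SEED, n_genes=200)
    data = simulate(spec)
    paths = write_dataset(data, OUT)
    print(f"simulated {len(data.genes)} genes on {spec.chrom} "
          f"({data.chrom_length:,} bp), seed {SEED}")
    for name, track in data.tracks.items():
        print(f"  {name:6s}: {track.total_mapped_reads:,} elements, "
              f"total signal {track.total_signal():,.0f}")
    print(f"  rna   : {len(data.rna_reads):,} reads "
          f"(declared library {data.rna_declared_total:,})")
    for name, path in paths.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
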