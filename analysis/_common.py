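"""Shared configuration for the numbered analysis drivers.

Every driver regenerates the same synthetic study (fixed seed) so each can be
run independently; outputs land under results/analysis/.
"""

from pathlib import Path

from exopair.peak_calling import SmoothingParams
from exopair.synthetic_data import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

SIM = SimConfig(n_chroms=4, chrom_length=1_500_000, n_genes=800, n_trna=60,
                divergent_fraction=0.5, tags_per_site_mean=30.0,
                background_rate=1.0, n_samples=4, seed=2024)

PARAMS = SmoothingParams()  # sigma 20 bp, exclusion zone 40 bp
MAX_SPAN = 80
MIN_TAGS = 4
TSS_MAX_DIST = 500


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
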