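"""Shared study configuration for the numbered analysis scripts.

One synthetic study world (the generator's default conditions: 20x20
grid of 385.9 km cells, 150 species with a strong Indo-Pacific-style
diversity hotspot, hotspot-avoiding MPA set) drives scripts 01-06.
Re-running any script with the same STUDY_SEED reproduces its outputs.
"""

from pathlib import Path

STUDY_SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"
WORLD_DIR = RESULTS / "world"

N_RANDOMIZATIONS = 1000   # SES-PD taxa-label randomizations
N_REPLICATES = 1000       # accumulation-curve replicates
K_CLUSTERS = 6
N_TOP = 3
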