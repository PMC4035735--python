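"""Shared study conditions for the numbered analysis drivers.

One planted-effect cohort (the "study cohort") is used by drivers 03-06;
its spec lives here so every driver regenerates exactly the same data.
"""

from pathlib import Path

from atrophymap.synthetic import CohortSpec, Ellipsoid

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: conditions of the worked synthetic study: 68 subjects (matching the
#: size of a typical single-site elderly imaging cohort), 20^3 grid at
#: 2 mm, ellipsoidal planted region, slope 0.01 per predictor Z
STUDY_SPEC = CohortSpec(
    n_subjects=68,
    grid_shape=(20, 20, 20),
    planted_region=Ellipsoid(center=(10.0, 10.0, 10.0), radii=(4.0, 4.0, 4.0)),
    effect_beta=0.01,
    hr_per_z={"fornix_fa": 0.38},
    baseline_hazard=0.04,
    seed=2014,
)

T_THRESHOLD = 3.5
N_PERM = 1000
ALPHA = 0.05
CONNECTIVITY = 26
PERM_SEED = 528
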