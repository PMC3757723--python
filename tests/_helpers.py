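"""Shared test fixtures: small synthetic subject rosters."""

import numpy as np

from tbmtools import SubjectRecord


def make_records(n, seed=0, missing_hcy=()):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        recs.append(
            SubjectRecord(
                subject_id=f"S{i:03d}",
                dose=int(rng.integers(0, 3)),
                age=float(rng.normal(75, 7)),
                sex=int(rng.integers(0, 2)),
                homocysteine=None if i in missing_hcy else float(rng.normal(11, 2)),
                folate=float(rng.normal(500, 100)),
                apoe4=int(rng.integers(0, 3)),
            )
        )
    return recs
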