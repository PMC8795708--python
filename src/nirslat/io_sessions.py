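"""Load a cohort directory (as written by ``nirslat simulate``) back into
in-memory :class:`~nirslat.simulate.SubjectData` records."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth, SubjectData
from .snirf_io import read_snirf

__all__ = ["load_subject_directory", "load_cohort_directory"]


def load_subject_directory(path: str | Path, subject_id: int = 0) -> SubjectData:
    """Read one subject's task/resting SNIRF files and behavior CSV."""
    path = Path(path)
    task_bundles, designs = {}, {}
    montage = None
    resting = None
    for f in sorted(path.glob("*.snirf")):
        montage_f, bundle, design = read_snirf(f)
        montage = montage or montage_f
        if f.stem == "resting" or design is None:
            resting = bundle
        else:
            task_bundles[f.stem] = bundle
            designs[f.stem] = design
    if not task_bundles:
        raise FileNotFoundError(f"no task SNIRF files under {path}")
    if resting is None:
        raise FileNotFoundError(f"no resting SNIRF file under {path}")
    beh_path = path / "behavior.csv"
    behavior = pd.read_csv(beh_path) if beh_path.exists() else pd.DataFrame()
    truth = GroundTruth({}, {}, {}, {}, np.zeros(0))
    return SubjectData(subject_id, montage, task_bundles, designs, resting,
                       behavior, truth)


def load_cohort_directory(path: str | Path):
    """Yield subjects from ``subject*/`` directories in numeric order."""
    path = Path(path)
    dirs = sorted(
        (d for d in path.iterdir() if d.is_dir() and d.name.startswith("subject")),
        key=lambda d: int(re.sub(r"\D", "", d.name) or 0),
    )
    if not dirs:
        raise FileNotFoundError(f"no subject directories under {path}")
    for d in dirs:
        yield load_subject_directory(d, int(re.sub(r"\D", "", d.name) or 0))
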