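"""Corpus-level orchestration: from recordings to MPS feature matrices.

Thin glue used by the examples and analysis scripts: compute each cry's
modulation power spectrum, flatten it (in dB relative to its own peak) into a
feature vector, and keep the per-cry labels alongside.
"""

from __future__ import annotations

import numpy as np

from .classify import CorpusFeatures
from .mps import mps_from_recording, to_db

__all__ = ["corpus_mps_features"]


def corpus_mps_features(recordings, **mps_kwargs) -> CorpusFeatures:
    """Flattened dB-scale MPS vector per recording, with labels.

    All recordings must share a sample rate so the MPS axes agree.
    """
    vectors, babies, conds, seqs = [], [], [], []
    shape = None
    for rec in recordings:
        m = mps_from_recording(rec, **mps_kwargs)
        if shape is None:
            shape = m.amplitude.shape
        elif m.amplitude.shape != shape:
            raise ValueError(
                "MPS shapes differ across recordings; use a common sample rate"
            )
        vectors.append(to_db(m).ravel())
        babies.append(rec.baby_id)
        conds.append(rec.condition)
        seqs.append(rec.sequence_id)
    return CorpusFeatures(
        X=np.vstack(vectors),
        baby_ids=np.array(babies),
        conditions=np.array(conds),
        sequence_ids=np.array(seqs),
    )
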