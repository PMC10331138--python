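"""EMA prompt scheduling and compliance simulation."""
from __future__ import annotations

from typing import List, Union

import numpy as np

from .types import DAY_S, MIN_S, EmaRecord, StudyDesign


def _rng(seed_or_rng: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_schedule(design: StudyDesign, seed) -> List[EmaRecord]:
    """Schedule ``n_days x len(anchors)`` signal-contingent prompts.

    Each prompt fires at its fixed anchor time plus a uniform jitter of
    +/- ``jitter_halfwidth_min`` minutes; prompts are returned sorted by time
    and unanswered.
    """
    rng = _rng(seed)
    records = []
    hw = design.jitter_halfwidth_min * MIN_S
    for day in range(design.n_days):
        for slot, anchor in enumerate(design.anchors_min, start=1):
            jitter = rng.uniform(-hw, hw) if hw > 0 else 0.0
            t = day * DAY_S + anchor * MIN_S + jitter
            records.append(EmaRecord(prompt_time=t, day_index=day, slot=slot))
    records.sort(key=lambda r: r.prompt_time)
    return records


def simulate_compliance(prompts: List[EmaRecord], p_answer: float, seed,
                        delay: str = "uniform", window_min: float = 60.0) -> List[EmaRecord]:
    """Mark each prompt answered independently with probability ``p_answer``.

    Answered prompts receive an answer time inside the 60-min response
    window; the delay law is uniform on [0, window] (``delay='uniform'``) —
    the study protocol fixes only the window, not the delay distribution.
    """
    if not (0 < p_answer <= 1):
        raise ValueError("p_answer must be in (0, 1]")
    if delay != "uniform":
        raise ValueError(f"unknown delay model {delay!r}")
    rng = _rng(seed)
    out = []
    for r in prompts:
        rec = EmaRecord(r.prompt_time, r.day_index, r.slot)
        # draw both variates unconditionally so the random stream does not
        # depend on the compliance outcome
        u_ans = rng.random()
        u_delay = rng.random()
        if u_ans < p_answer:
            rec.answer_time = r.prompt_time + u_delay * window_min * MIN_S
        out.append(rec)
    return out
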