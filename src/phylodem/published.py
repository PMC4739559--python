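"""Published per-sample times at maximum growth rate.

Times (kya) at which each drainage-basin or clade sample of Changtang
Plateau schizothoracines reached its maximum skyline growth rate, as
reported by the source study's Bayesian skyline analyses. They are inputs
to the pulse-clustering procedure: with 1-kyr bins and a 10-kyr gap rule
they resolve into three expansion pulses (post-LGM, late MIS 3, early
MIS 3).
"""

from __future__ import annotations

# (sample, time at maximum growth rate in kya)
GROWTH_RATE_TIMES_KYA: tuple[tuple[str, float], ...] = (
    ("Pangong Co", 2.4),
    ("Tarok Co", 14.9),
    ("Zhari Nam Co", 5.7),
    ("Dagwa Co", 4.3),
    ("Dong Co", 3.8),
    ("Tuksitugar Co", 8.9),
    ("Kang Co", 5.4),
    ("Tangra Yum Co", 5.8),
    ("Ngangtse Co", 11.6),
    ("Siling Co", 36.7),
    ("Siling Co (recent phase)", 6.1),
    ("Pongok Co", 4.3),
    ("Gomang Co", 6.8),
    ("Nam Co", 11.5),
    ("Bam Co", 3.1),
    ("Amdo Tsonak Co", 9.1),
    ("Southern Tibetan lakes", 8.9),
    ("Tsangpo", 61.4),
    ("Upper Salween", 31.0),
    ("Upper Indus", 56.2),
    ("Upper Yangtze", 64.7),
    ("Clade WT", 39.6),
    ("Subclade NET-E", 8.3),
    ("Subclade CT-C", 4.5),
    ("Subclade CT-E", 54.8),
    ("Subclade CT-E (recent phase)", 12.0),
)


def growth_time_values() -> list[float]:
    """The published t_max values (kya) as a plain list."""
    return [t for _, t in GROWTH_RATE_TIMES_KYA]
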