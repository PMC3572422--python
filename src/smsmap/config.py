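"""Mapper configuration shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class MapperConfig:
    """Tunable parameters of the successive-refinement mapper.

    K:              minimum anchor length for suffix-array anchoring.
    lcp_shorten:    bases trimmed off each located LCP (anchors end one base
                    short of the LCP by default, avoiding matches that end in
                    a sequencing error).
    max_count:      anchors whose sequence occurs more often than this in the
                    genome are discarded.
    max_candidates: number of ranked clusters carried into refinement and the
                    mapping-quality denominator.
    delta:          assumed maximum insertion rate; flanks of candidate
                    intervals are scaled by (1 + delta).
    k_sdp:          fixed match length for sparse dynamic programming.
    b_sdp:          half-width of the guide band around chained SDP matches.
    mismatch_prior / deletion_prior: phred-scaled penalties used when the
                    per-base alternative call does not explain the event.
    flat_*:         penalties used when a read carries no quality tracks.
    """

    K: int = 12
    lcp_shorten: int = 1
    max_count: int = 10000
    max_candidates: int = 10
    delta: float = 0.15
    k_sdp: int = 11
    b_sdp: int = 15
    mismatch_prior: int = 20
    deletion_prior: int = 15
    flat_insertion: int = 15
    flat_deletion: int = 15
    flat_mismatch: int = 20
    threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.k_sdp < 1 or self.b_sdp < 1:
            raise ValueError("K, k_sdp and b_sdp must be positive")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if self.lcp_shorten < 0 or self.max_count < 1:
            raise ValueError("invalid lcp_shorten / max_count")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "MapperConfig":
        """Read a key=value config file; keyword overrides win."""
        known = {f.name: f.type for f in fields(cls)}
        values: dict = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
                key, _, val = line.partition("=")
                key = key.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                values[key] = float(val) if key == "delta" else int(val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)
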