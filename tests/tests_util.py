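"""Shared helpers for driving the object-level World API in tests."""
from matesim import generation_turnover, place_males, run_season


def run_world_generations(world, generations=None):
    """Drive a World through full generations exactly the way the fast
    kernel does: the world's initial dispersal serves as the first
    season's placement, later seasons re-disperse explicitly.

    Returns the list of per-season SeasonSummary records.
    """
    p = world.params
    if generations is None:
        generations = p.generations
    summaries = []
    first = True
    for _gen in range(generations):
        for _s in range(p.longevity):
            if not first:
                place_males(world)
            first = False
            summaries.append(run_season(world))
        generation_turnover(world)
    return summaries
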