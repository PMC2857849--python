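import numpy as np
import pytest

import snpblup as sb


@pytest.fixture
def tiny_pedigree() -> sb.Pedigree:
    """S, D founders; K their offspring; M from the S x K mating."""
    return sb.Pedigree.from_records(
        [("S", None, None), ("D", None, None), ("K", "S", "D"), ("M", "S", "K")]
    )


def small_config(**overrides) -> sb.SimulationConfig:
    """A compact population: 156 animals, final generation of 108 masked."""
    base = dict(
        n_founders=12,
        n_generations=3,
        offspring_per_mating=6,
        n_chromosomes=3,
        snps_per_chromosome=40,
        n_qtl=12,
        n_validation_unphenotyped=108,
        seed=11,
    )
    base.update(overrides)
    return sb.SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_population() -> sb.TruePopulation:
    return sb.simulate_population(small_config())


def ordering_config(seed: int) -> sb.SimulationConfig:
    """Population size used for multi-seed accuracy comparisons (260 animals,
    180 masked); large enough for stable metrics, small enough to run many
    seeds quickly."""
    return sb.SimulationConfig(
        n_founders=20,
        n_generations=3,
        offspring_per_mating=6,
        n_validation_unphenotyped=180,
        seed=seed,
    )


@pytest.fixture(scope="session")
def multi_seed_results(tmp_path_factory) -> list[sb.PipelineResult]:
    """Full-pipeline runs (all three methods) over 10 seeds."""
    out = tmp_path_factory.mktemp("ordering")
    results = []
    for seed in range(10):
        cfg = sb.RunConfig(
            simulation=ordering_config(seed),
            seed=seed,
            output_dir=str(out / f"seed{seed}"),
        )
        results.append(sb.run_pipeline(cfg))
    return results


def random_pedigree(rng: np.random.Generator, n: int) -> sb.Pedigree:
    """Random sorted pedigree of n individuals, possibly inbred."""
    recs = []
    for k in range(n):
        if k < 2 or rng.random() < 0.3:
            recs.append((f"i{k}", None, None))
        else:
            s, d = rng.choice(k, size=2, replace=False)
            recs.append((f"i{k}", f"i{s}", f"i{d}"))
    return sb.Pedigree.from_records(recs)
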