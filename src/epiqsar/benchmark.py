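"""One-call runner for the default synthetic benchmark.

Generates the seeded 250-compound-per-module libraries, featurizes every
descriptor set, runs the full 180-config grid with ten-fold CV, selects the
best model per module, and reports external-test metrics — the same
end-to-end path the command-line pipeline drives stage by stage.
"""

from __future__ import annotations

from dataclasses import dataclass

from epiqsar.datasets import RegulatorModule
from epiqsar.featurization import DescriptorSet, FeatureMatrix, featurize
from epiqsar.models import GridResult, ModelConfig, evaluate_grid, select_best
from epiqsar.synthetic import GeneratorConfig, SyntheticLibrary, generate_library


@dataclass
class BenchmarkResult:
    library: SyntheticLibrary
    features: dict[tuple[RegulatorModule, DescriptorSet], FeatureMatrix]
    grid: GridResult
    best: dict[RegulatorModule, ModelConfig]
    test_accuracy: dict[RegulatorModule, float]

    @property
    def min_test_accuracy(self) -> float:
        return min(self.test_accuracy.values())


def featurize_modules(
    library: SyntheticLibrary, descriptor_sets=None
) -> dict[tuple[RegulatorModule, DescriptorSet], FeatureMatrix]:
    descriptor_sets = descriptor_sets or list(DescriptorSet)
    return {
        (module, dset): featurize(library.libraries[module], dset)
        for module in library.libraries
        for dset in descriptor_sets
    }


def run_benchmark(
    seed: int,
    n_per_module: int = 250,
    label_noise: float = 0.1,
    folds: int = 10,
    descriptor_sets=None,
    algorithms=None,
) -> BenchmarkResult:
    """Generate, featurize, benchmark, and select — the full modeling path."""
    library = generate_library(
        GeneratorConfig(seed=seed, n_per_module=n_per_module, label_noise=label_noise)
    )
    features = featurize_modules(library, descriptor_sets)
    from epiqsar.models import Algorithm, enumerate_grid

    sets = descriptor_sets or list(DescriptorSet)
    algos = algorithms or list(Algorithm)
    configs = enumerate_grid(list(RegulatorModule), algos, sets, seed=seed)
    grid = evaluate_grid(features, library.labels, configs=configs,
                         folds=folds, seed=seed)
    best, test_accuracy = {}, {}
    by_config = {e.config: e for e in grid.entries}
    for module in RegulatorModule:
        config = select_best(grid, module)
        best[module] = config
        test_accuracy[module] = by_config[config].test.ACC
    return BenchmarkResult(
        library=library, features=features, grid=grid,
        best=best, test_accuracy=test_accuracy,
    )
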