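"""The five fibril topology classes and induced fibrillar components.

Builds the ideal fibril graph of every class, classifies each, and shows
the worked component-merging example: binding two equal 1-ribbons end to
end halves the induced component count and doubles the maximum size.
"""

from fibrilnet import (
    TEMPLATES,
    classify_topology,
    get_template,
    ideal_fibril,
    induced_fibrillar_components,
    make_fixture,
    nucleation_threshold,
)

print(f"{'class':<22} {'subunit':>7} {'threshold':>9}  n(12 subunits)  label")
for name in TEMPLATES:
    t = get_template(name)
    g = ideal_fibril(t, 12)
    print(
        f"{name:<22} {t.subunit_size:>7} {nucleation_threshold(t):>9}"
        f"  {g.n:>13}  {classify_topology(g)}"
    )

print("\nend-to-end joining of two 10-mer 1-ribbons:")
joined = make_fixture("two_fibrils_joined", template="1-ribbon", length=10)
single = ideal_fibril("1-ribbon", 10)
before = induced_fibrillar_components(single, "1-ribbon")
after = induced_fibrillar_components(joined, "1-ribbon")
print(f"  one fibril : count={before.count}, max size={before.max_size}")
print(f"  joined pair: count={after.count}, max size={after.max_size}")
# One bond between two terminal monomers fuses the two induced fibrillar
# components into one (count 2 -> 1) while doubling the largest component
# (10 -> 20 monomers) - the elementary consolidation step of fibril growth.
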