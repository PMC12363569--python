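"""Build a similarity-organized feature-image template and render a protein.

Descriptors correlated across a reference corpus become spatial
neighbours on the grid, giving convolutions something local to see.
"""

from locforge import DescriptorConfig, build_template, feature_table, render_image
from locforge.descriptors import FeatureVector
from locforge.synthetic import SyntheticSpec, generate_dataset

records = generate_dataset(SyntheticSpec(n_proteins=60, length_range=(40, 120), seed=1))
config = DescriptorConfig(families=("AAC", "DPC"))
table = feature_table({r.id: r.sequence for r in records}, config)

template = build_template(table, method="mds", seed=0)
print(f"template: {template.grid_height}x{template.grid_width} grid, "
      f"{len(template.placement)} descriptors placed")

fv = FeatureVector(list(table.columns), table.iloc[0].to_numpy())
image = render_image(fv, template)
print(f"rendered image for {table.index[0]}: "
      f"{int((image.pixels > 0).sum())} nonzero pixels, "
      f"pixel sum {image.pixels.sum():.3f} (sum of placed normalized values)")
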