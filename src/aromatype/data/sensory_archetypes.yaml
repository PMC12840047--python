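# Default QDA archetype profiles for the three rice aroma types, on the 0-9
# intensity scale over the ten panel attributes. Values are a qualitative
# reconstruction of the published spider plots (numbers are not printed there):
# type A = sweet/popcorn/grassy-forward with no floral note, type B =
# cereal/starchy with strongly reduced sweet and popcorn notes, type C =
# balanced-high "complex" profile, elevated across floral, woody, oatmeal,
# dairy and corn as well as the cereal notes. The three profiles are roughly
# equidistant in attribute space, as the published dendrogram and WCSS elbow
# at three clusters imply.
attributes:
  - starchy
  - grainy
  - floral
  - popcorn
  - sweet
  - grassy
  - woody
  - oatmeal
  - dairy
  - corn
archetype_means:
  A: [4.0, 6.0, 0.5, 7.0, 7.5, 5.5, 2.0, 2.5, 2.0, 3.0]
  B: [6.5, 7.0, 1.0, 2.0, 2.5, 2.5, 3.5, 3.5, 2.0, 3.0]
  C: [6.0, 6.0, 3.0, 5.0, 5.5, 3.0, 4.0, 5.0, 4.0, 5.5]
noise_sd: 0.5
sample_sd: 0.25
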