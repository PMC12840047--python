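descriptor	definition	reference_substance
Starchy	Aroma of bread and flour	Boiled starch:water (1:5) and cool
Grainy	a flavor reminiscent of raw grain	28 mg/kg Butyraldehyde
Floral	The smell produced by a non-specific type of flower	1600 mg/kg phenethyl alcohol
Popcorn	aroma of popcorn	1300 mg/kg 2-Acetyl-1-pyrrolidine
Sweet	aroma of Demerara sugar	255 mg/kg 4-Hydroxy-2,5-dimethylfuran-3-one
Grassy	A green, slightly earthy, and slightly sweet flavor	26.3 mg/kg 1-Octanol
Woody	aroma of the dry, freshly cut wood smell	Toothpick
Oatmeal	aroma of cooked oatmeal	Quaker Oatmeal (Quaker, London, UK)
Dairy	aroma of uncooked milk	High-quality 2% Brand pasteurized milk
Corn	aroma of canned creamed corn	Cream Style Sweet Corn
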