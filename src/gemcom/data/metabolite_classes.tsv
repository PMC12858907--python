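# Default metabolite class table for cross-feeding annotation.
# Ids cover commonly exchanged compounds plus the toy-model ids.
metabolite_id	class
glc	carbohydrate
glc_e	carbohydrate
glucose	carbohydrate
fru	carbohydrate
suc	carbohydrate
rib	carbohydrate
cit	organic_acid
cit_e	organic_acid
citrate	organic_acid
ace	organic_acid
ace_e	organic_acid
acetate	organic_acid
fum	organic_acid
fum_e	organic_acid
fumarate	organic_acid
succ	organic_acid
succinate	organic_acid
lac	organic_acid
mal	organic_acid
pyr	organic_acid
palmitate	organic_acid
myristate	organic_acid
his	amino_acid
glu	amino_acid
phe	amino_acid
fmet	amino_acid
gly	amino_acid
pro	amino_acid
ala	amino_acid
ser	amino_acid
thr	amino_acid
met	amino_acid
trp	amino_acid
vit	vitamin
vit_e	vitamin
thiamine	vitamin
thm	vitamin
niacin	vitamin
nac	vitamin
ergocalciferol	vitamin
vitd2	vitamin
btn	vitamin
amp	nucleotide
adn	nucleotide
gua	nucleotide
ura	nucleotide
cytd	nucleotide
ins	nucleotide
nh4	other
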