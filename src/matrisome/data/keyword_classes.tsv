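keyword	functional_class
hydrolase	acting_on_polysaccharides
glycoside hydrolase	acting_on_polysaccharides
glycosyl hydrolase	acting_on_polysaccharides
esterase	acting_on_polysaccharides
pectin methylesterase	acting_on_polysaccharides
lyase	acting_on_polysaccharides
pectate lyase	acting_on_polysaccharides
chitinase	acting_on_polysaccharides
expansin	acting_on_polysaccharides
glucanase	acting_on_polysaccharides
xyloglucan endotransglucosylase	acting_on_polysaccharides
galactosidase	acting_on_polysaccharides
glucosidase	acting_on_polysaccharides
protease	protease
proteinase	protease
peptidase	protease
amidase	protease
subtilase	protease
subtilisin	protease
aspartic protease	protease
cysteine protease	protease
serine carboxypeptidase	protease
peroxidase	oxidoreductase
oxidase	oxidoreductase
berberine-bridge enzyme	oxidoreductase
berberine bridge enzyme	oxidoreductase
laccase	oxidoreductase
oxidoreductase	oxidoreductase
multicopper oxidase	oxidoreductase
blue copper protein	oxidoreductase
lipase	lipid_metabolism
GDSL lipase	lipid_metabolism
lipid transfer protein	lipid_metabolism
LTP	lipid_metabolism
phospholipase	lipid_metabolism
pectinesterase inhibitor	interacting_domains
LRR	interacting_domains
leucine-rich repeat	interacting_domains
lectin	interacting_domains
enzyme inhibitor	interacting_domains
protease inhibitor	interacting_domains
proteinase inhibitor	interacting_domains
PMEI	interacting_domains
arabinogalactan protein	signaling
AGP	signaling
fasciclin	signaling
receptor kinase	signaling
wall-associated kinase	signaling
WAK	signaling
COBRA	signaling
extensin	structural
glycine-rich protein	structural
proline-rich protein	structural
hydroxyproline-rich glycoprotein	structural
HRGP	structural
structural protein	structural
germin	miscellaneous
dirigent	miscellaneous
glycolytic enzyme	miscellaneous
enolase	miscellaneous
phosphatase	miscellaneous
purple acid phosphatase	miscellaneous
thaumatin	miscellaneous
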