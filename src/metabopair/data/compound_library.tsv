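name	formula	compound_class	standard_confirmed	msms_match
Creatinine	C4H7N3O	Alpha amino acids and derivatives	False	False
Hydrogen phosphate	H3O4P	Non-metal phosphates	False	False
Pregabalin	C8H17NO2	Gamma amino acids and derivatives	False	False
DL-2-Aminooctanoic acid	C8H17NO2	Alpha amino acids	False	False
Methacholine	C8H17NO2	Tetraalkylammonium salts	False	False
Propionylcholine	C8H17NO2	Acyl cholines	False	False
L-isoleucyl-L-proline	C11H20N2O3	Dipeptides	True	True
1-Methylhypoxanthine	C6H6N4O	Hypoxanthines	False	False
7-Methylhypoxanthine	C6H6N4O	Hypoxanthines	False	False
1,6-Hexanedithiol	C6H14S2	Alkythiols	False	False
N1-Methyl-2-pyridone-5-carboxamide	C7H8N2O2	Nicotinamides	False	False
N-methyl-4-pyridone-3-carboxamide	C7H8N2O2	Nicotinamides	False	False
2-Amino-4-nitrotoluene	C7H8N2O2	Nitrobenzenes	True	True
2-benzoxazolol	C7H5NO2	Benzoxazolones	True	True
N-(3-acetamidopropyl)pyrrolidin-2-one	C9H16N2O2	N-alkylpyrrolidines	False	False
4-(2-chloro-1,2-diphenylethenyl)phenol	C20H15ClO	Stilbenes	False	False
1-Aminocyclopropanecarboxylic acid	C4H7NO2	Alpha amino acids	False	False
(S)-2-Azetidinecarboxylic acid	C4H7NO2	Alpha amino acids	False	False
p-Cresol	C7H8O	Cresols	False	False
m-Cresol	C7H8O	Cresols	False	False
o-Cresol	C7H8O	Cresols	False	False
Benzyl alcohol	C7H8O	Benzyl alcohols	False	False
Anisole	C7H8O	Anisoles	False	False
N-(Carbethoxyacetyl)-4-chloro-L-tryptophan	C16H17ClN2O5	N-acyl-alpha amino acids	False	False
7-Chloro-6-demethylcepharadione B	C18H12ClNO4	Oligosaccharides	True	True
Acetyl-N-formyl-5-methoxykynurenamine	C13H16N2O4	Alkyl-phenylketones	True	True
N(2)-phenylacetyl-L-glutaminate	C13H16N2O4	Glutamine and derivatives	False	False
3',4'-Dihydrodiol	C15H14N2O4	Phenylhydantoins	True	True
Nonane	C9H20	Branched alkanes	False	False
2,3,4-Trimethylhexane	C9H20	Branched alkanes	False	False
Trimethylamine N-oxide (TMAO)	C3H9NO	Trialkyl amine oxides	False	False
1-Amino-propan-2-ol	C3H9NO	1,2-aminoalcohols	False	False
1-Methyl-2-pyrrolecarboxaldehyde	C6H7NO	Aryl-aldehydes	False	False
2-Acetylpyrrole	C6H7NO	Aryl alkyl ketones	False	False
4-Aminophenol	C6H7NO	Aniline and substituted anilines	False	False
2,3,4,5-Tetrahydro-2-pyridinecarboxylic acid	C6H9NO2	Alpha amino acids and derivatives	False	False
4-Methyleneproline	C6H9NO2	Proline and derivatives	False	False
1-Piperideine-2-carboxylic acid	C6H9NO2	Tetrahydropyridines	False	False
Phenol	C6H6O	1-hydroxy-4-unsubstituted benzenoids	False	False
Vinylfuran	C6H6O	Furans	False	False
4-Hydroxybenzaldehyde	C7H6O2	Hydroxybenzaldehydes	False	False
Benzoic acid	C7H6O2	Benzoic acids	False	False
Nitrososulfamethoxazole	C10H9N3O4S	Benzenesulfonamides and derivates	False	False
Hippuric acid	C9H9NO3	Hippuric acids	False	False
Adrenochrome	C9H9NO3	Indoles and derivates	False	False
3-Succinoylpyridine	C9H9NO3	Gamma-keto acids and derivatives	False	False
3-hydroxydecanoyl carnitine	C17H31NO4	Acyl carnitines	False	False
9-Decenoylcarnitine	C17H33NO5	Acyl carnitines	False	False
2,5-Dihydro-2,4,5-trimethyloxazole	C6H11NO	Oxazolines	True	True
2-Acetylpyrrolidine	C6H11NO	Pyrrolidines	False	False
Epsilon-caprolactam	C6H11NO	Caprolactams	False	False
1-Piperidinecarboxaldehyde	C6H11NO	Piperidines	False	False
L-Isoleucine	C6H13NO2	Amino acids, peptides, and analogues	False	False
L-Leucine	C6H13NO2	Amino acids, peptides, and analogues	False	False
L-Norleucine	C6H13NO2	Amino acids, peptides, and analogues	False	False
Aminocaproic acid	C6H13NO2	Fatty acids and conjugates	False	False
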