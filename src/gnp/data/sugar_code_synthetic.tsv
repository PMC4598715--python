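# Synthetic reconstruction of a deoxysugar biosynthetic code: sugar name,
# class, SMILES with a [*:1] anomeric attachment point, and the
# semicolon-joined sugar-gene families required for its biosynthesis.
# Built from published glycogenomics logic; user-replaceable. Stereochemistry
# is not encoded (diastereomers such as mycaminose/ravidosamine share a
# constitution and a gene-family set).
name	class	smiles	gene_families
mycaminose	deoxyhexose	[*:1]C1OC(C)C(O)C(N(C)C)C1O	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;3,4-isomerase;3-aminotransferase;N,N-dimethyltransferase
ravidosamine	deoxyhexose	[*:1]C1OC(C)C(O)C(N(C)C)C1O	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;3,4-isomerase;3-aminotransferase;N,N-dimethyltransferase
mycosamine	deoxyhexose	[*:1]C1OC(C)C(O)C(N)C1O	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;3,4-isomerase;3-aminotransferase
desosamine	deoxyhexose	[*:1]C1CC(N(C)C)CC(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;3,4-dehydratase;3-aminotransferase;N,N-dimethyltransferase
angolosamine	deoxyhexose	[*:1]C1CC(N(C)C)C(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;3-aminotransferase;N,N-dimethyltransferase;4-ketoreductase
vancosamine	deoxyhexose	[*:1]C1CC(C)(N)C(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;3-aminotransferase;C-methyltransferase;4-ketoreductase
acosamine	deoxyhexose	[*:1]C1CC(N)C(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;3-aminotransferase;4-ketoreductase
daunosamine	deoxyhexose	[*:1]C1CC(N)C(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;3-aminotransferase;4-ketoreductase;5-epimerase
perosamine	deoxyhexose	[*:1]C1OC(C)C(N)C(O)C1O	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;4-aminotransferase
mycarose	deoxyhexose	[*:1]C1CC(C)(O)C(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;C-methyltransferase;3-ketoreductase;4-ketoreductase;5-epimerase
cladinose	deoxyhexose	[*:1]C1CC(C)(OC)C(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;C-methyltransferase;3-ketoreductase;4-ketoreductase;5-epimerase;O-methyltransferase
olivose	deoxyhexose	[*:1]C1CC(O)C(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;3-ketoreductase;4-ketoreductase
oliose	deoxyhexose	[*:1]C1CC(O)C(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;3-ketoreductase;4-ketoreductase;3,5-epimerase
digitoxose	deoxyhexose	[*:1]C1CC(O)C(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;3-ketoreductase;5-epimerase
rhodinose	deoxyhexose	[*:1]C1CCC(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;2,3-reductase;4-ketoreductase;5-epimerase
amicetose	deoxyhexose	[*:1]C1CCC(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;2,3-reductase;4-ketoreductase
forosamine	deoxyhexose	[*:1]C1CCC(N(C)C)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;2,3-reductase;4-aminotransferase;N,N-dimethyltransferase
chalcose	deoxyhexose	[*:1]C1CC(OC)C(O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;3-ketoreductase;4-ketoreductase;O-methyltransferase
rhamnose	deoxyhexose	[*:1]C1OC(C)C(O)C(O)C1O	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;3,5-epimerase;4-ketoreductase
quinovose	deoxyhexose	[*:1]C1OC(C)C(O)C(O)C1O	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;4-ketoreductase
4-O-acetylolivose	deoxyhexose	[*:1]C1CC(O)C(OC(C)=O)C(C)O1	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;2,3-dehydratase;3-ketoreductase;4-ketoreductase;4-O-acetyltransferase
3-N-methylmycosamine	deoxyhexose	[*:1]C1OC(C)C(O)C(NC)C1O	glucose-1-phosphate-thymidylyltransferase;4,6-dehydratase;3,4-isomerase;3-aminotransferase;N-methyltransferase
xylose	pentose	[*:1]C1OCC(O)C(O)C1O	UDP-glucose-dehydrogenase;UDP-glucose-decarboxylase
madurose	pentose	[*:1]C1OCC(C)(O)C(N)C1O	UDP-glucose-dehydrogenase;UDP-glucose-decarboxylase;C-methyltransferase;3-aminotransferase
aminopentose	pentose	[*:1]C1OCC(O)C(N)C1O	UDP-glucose-dehydrogenase;UDP-glucose-decarboxylase;3-aminotransferase
glucose	hexose	[*:1]C1OC(CO)C(O)C(O)C1O
mannose	hexose	[*:1]C1OC(CO)C(O)C(O)C1O
gulose	hexose	[*:1]C1OC(CO)C(O)C(O)C1O
N-acetylglucosamine	hexose	[*:1]C1OC(CO)C(O)C(O)C1NC(C)=O
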