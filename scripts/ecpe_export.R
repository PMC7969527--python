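#!/usr/bin/env Rscript
# Export the ECPE response data (2,922 x 28 dichotomous items) from the CDM
# R package to the delimited format read by `qamrm fit`.
#
# Requires the CDM package (install.packages("CDM")); network access is needed
# the first time.  Usage:
#
#   Rscript scripts/ecpe_export.R ecpe_responses.csv
#
# Then, for the hierarchical compensatory analysis (lexical before cohesive
# before morphosyntactic):
#
#   qamrm fit ecpe_responses.csv src/qamrm/data/ecpe_qmatrix.csv \
#       --mode compensatory --hierarchy "a3<a2<a1" --out ecpe_fit
args <- commandArgs(trailingOnly = TRUE)
out <- if (length(args) >= 1) args[[1]] else "ecpe_responses.csv"
suppressPackageStartupMessages(library(CDM))
data(data.ecpe, package = "CDM")
resp <- data.ecpe$data[, -1]  # drop the id column
colnames(resp) <- paste0("item", seq_len(ncol(resp)))
write.csv(resp, out, row.names = FALSE)
cat(sprintf("wrote %d x %d responses to %s\n", nrow(resp), ncol(resp), out))
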