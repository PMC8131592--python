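# Penalized-spline GAM fit for canopy-anomaly attribution (mgcv backend).
#
# Usage: Rscript fit_gam.R <data.csv> <outdir> <formula>
#
# data.csv must contain: delta plus the covariates named in the formula
# (gaf, dtw, bh, x, y as available).  Writes to <outdir>:
#   summary.json    n, deviance explained, smooth-term table (edf, F, p)
#   curves.csv      per covariate: dense grid with full prediction (others
#                   at their medians, x/y at the centroid) and the centered
#                   partial-effect term with its SE
#   terms_at_data.csv  per-row term contributions at the training data
suppressPackageStartupMessages({
  library(mgcv)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
stopifnot(length(args) == 3)
data_path <- args[1]
outdir <- args[2]
formula_str <- args[3]

d <- read.csv(data_path)
form <- as.formula(formula_str)
m <- gam(form, data = d, method = "REML")
s <- summary(m)

st <- as.data.frame(s$s.table)
st$term <- rownames(st)
names(st) <- c("edf", "ref_df", "statistic", "p_value", "term")

write_json(
  list(
    n = nrow(d),
    deviance_explained = unname(s$dev.expl),
    r_sq = unname(s$r.sq),
    aic = AIC(m),
    terms = st
  ),
  file.path(outdir, "summary.json"),
  digits = 12, auto_unbox = TRUE
)

covars <- intersect(c("gaf", "dtw", "bh"), all.vars(form))
ngrid <- 401
curves <- list()
for (v in covars) {
  nd <- data.frame(row.names = seq_len(ngrid))
  for (u in covars) {
    nd[[u]] <- if (u == v) seq(min(d[[u]]), max(d[[u]]), length.out = ngrid)
               else rep(median(d[[u]]), ngrid)
  }
  if ("x" %in% all.vars(form)) {
    nd$x <- rep(mean(d$x), ngrid)
    nd$y <- rep(mean(d$y), ngrid)
  }
  pf <- predict(m, nd, se.fit = TRUE)
  pt <- predict(m, nd, type = "terms", se.fit = TRUE)
  tname <- paste0("s(", v, ")")
  tcol <- which(colnames(pt$fit) == tname)
  curves[[v]] <- data.frame(
    variable = v, value = nd[[v]],
    pred = as.numeric(pf$fit), pred_se = as.numeric(pf$se.fit),
    term_fit = if (length(tcol)) as.numeric(pt$fit[, tcol]) else NA_real_,
    term_se = if (length(tcol)) as.numeric(pt$se.fit[, tcol]) else NA_real_
  )
}
write.csv(do.call(rbind, curves), file.path(outdir, "curves.csv"),
          row.names = FALSE)

tad <- as.data.frame(predict(m, type = "terms"))
tad$fitted <- fitted(m)
write.csv(tad, file.path(outdir, "terms_at_data.csv"), row.names = FALSE)
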